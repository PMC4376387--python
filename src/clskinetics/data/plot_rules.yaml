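# Qualitative plot-signature rules mapping dose-response-parameter plot
# properties (vs cofactor F) to predicted (mechanism, position) pairs for F
# and the steroid receptor (GR).
#
# Mechanism codes: A accelerator; D any decelerator; C/U/N competitive /
# uncompetitive / noncompetitive; L/P linear / partial; two-letter codes are
# atomic subtypes.  Positions are relative to the concentration-limited
# step.  rel: GR-after-F | GR-before-F | same-step | any.
#
# The table is a set of *sufficient* conditions and is not complete.
# Footnote constraints (applied as a post-filter, not encoded per entry):
# two cofactors cannot be of the same type at the same step; GR does not
# repress as an accelerator before the CLS.
entries:
  - id: 1
    when: {amax_dir: const}
    predictions:
      - {f_mech: any, f_pos: any, gr_mech: [A], gr_pos: [after], rel: [GR-before-F, same-step]}
      - {f_mech: [U], f_pos: [after], gr_mech: any, gr_pos: any, rel: [GR-after-F]}
    text: "F is any activity after or at GR and GR is A after CLS; or F is U after CLS and GR is any activity after F"
  - id: 2
    when: {amax_linear_origin: true, amax_dir: inc}
    predictions:
      - {f_mech: [A], f_pos: [at], gr_mech: any, gr_pos: any, rel: any}
    text: "F is A at CLS"
  - id: 3
    when: {amax_nonlinear_origin: true, amax_dir: inc}
    predictions:
      - {f_mech: [A], f_pos: [before], gr_mech: any, gr_pos: any, rel: any}
    text: "F is A before CLS"
  - id: 4
    when: {amax_dir: dec, amax_approaches_zero: true}
    predictions:
      - {f_mech: [C, L], f_pos: [before, at], gr_mech: [A], gr_pos: [after], rel: any}
      - {f_mech: [C, L], f_pos: [before, at], gr_mech: [D], gr_pos: [before, at], rel: any}
    text: "F is C or L before or at the CLS; GR is A after CLS or D before/at CLS"
  - id: 5
    when: {amax_dir: inc, amin_dir: inc, amax_nonlinear: true, amin_nonlinear: true,
           amax_positive_true_zero: true, amin_positive_true_zero: true}
    predictions:
      - {f_mech: [A], f_pos: [after], gr_mech: [A], gr_pos: [after], rel: [GR-after-F]}
      - {f_mech: [A], f_pos: [after], gr_mech: [D], gr_pos: any, rel: any}
      - {f_mech: [PU, PN], f_pos: [before, at], gr_mech: any, gr_pos: any, rel: any}
      - {f_mech: [C], f_pos: [after], gr_mech: [A], gr_pos: [after], rel: [GR-after-F]}
      - {f_mech: [C], f_pos: [after], gr_mech: [D], gr_pos: any, rel: any}
    text: "Amax and Amin nonlinear increasing, positive at true zero of F"
  - id: 6
    when: {amax_dir: dec, amax_nonlinear: true, amax_positive_limit: true}
    predictions:
      - {f_mech: [A], f_pos: [after], gr_mech: [A], gr_pos: [after], rel: [GR-after-F]}
      - {f_mech: [A], f_pos: [after], gr_mech: [D], gr_pos: any, rel: any}
      - {f_mech: [PU, PN], f_pos: [before, at], gr_mech: any, gr_pos: any, rel: any}
      - {f_mech: [C], f_pos: [after], gr_mech: [A], gr_pos: [after], rel: [GR-after-F]}
      - {f_mech: [C], f_pos: [after], gr_mech: [D], gr_pos: any, rel: any}
    text: "Amax nonlinear decreasing, does not approach zero for infinite F"
  - id: 7
    when: {amax_dir: inc, amin_dir: dec}
    predictions:
      - {f_mech: [A], f_pos: [after], gr_mech: [A, C], gr_pos: any, rel: [GR-after-F]}
    text: "F is A after CLS and GR is A or C, after F"
  - id: 8
    when: {amin_linear_origin: true, amin_dir: inc}
    predictions:
      - {f_mech: [A], f_pos: [at], gr_mech: any, gr_pos: any, rel: any}
    text: "F is A at the CLS"
  - id: 9
    when: {amin_nonlinear_origin: true, amin_dir: inc}
    predictions:
      - {f_mech: [A], f_pos: [before], gr_mech: any, gr_pos: any, rel: any}
    text: "F is A before CLS"
  - id: 10
    when: {amin_positive_true_zero: true}
    predictions:
      - {f_mech: [A], f_pos: [after], gr_mech: any, gr_pos: any, rel: any}
      - {f_mech: [PU, PN], f_pos: [before, at], gr_mech: any, gr_pos: any, rel: any}
    text: "F is A after CLS; or F is PU or PN before or at CLS"
  - id: 11
    when: {amin_dir: dec, amin_approaches_zero: true}
    predictions:
      - {f_mech: [C, LU, LN], f_pos: [before, at], gr_mech: any, gr_pos: any, rel: any}
    text: "F is C, LU, or LN, before or at CLS"
  - id: 12
    when: {h_amin_vs_amax: "<"}
    predictions:
      - {f_mech: [A], f_pos: [after], gr_mech: [A], gr_pos: [after], rel: [GR-after-F]}
      - {f_mech: [C, L], f_pos: [before], gr_mech: [A], gr_pos: [after], rel: any}
    text: "H of Amin < H of Amax"
  - id: 13
    when: {h_amin_vs_amax: ">"}
    predictions:
      - {f_mech: [A], f_pos: [before], gr_mech: [C, L], gr_pos: [before], rel: [same-step]}
      - {f_mech: [A], f_pos: [after], gr_mech: [D], gr_pos: [before, at], rel: any}
      - {f_mech: [C], f_pos: [after], gr_mech: [A], gr_pos: [after], rel: [same-step]}
      - {f_mech: [C, L], f_pos: [at], gr_mech: any, gr_pos: any, rel: any}
      - {f_mech: [C], f_pos: [before], gr_mech: [A], gr_pos: [after], rel: any}
    text: "H of Amin > H of Amax"
  - id: 14
    when: {h_recip_amin_vs_amax: "<"}
    predictions:
      - {f_mech: [A], f_pos: [after], gr_mech: [A], gr_pos: [after], rel: [GR-after-F]}
    text: "H of 1/Amin < H of 1/Amax"
  - id: 15
    when: {h_recip_amin_vs_amax: ">"}
    predictions:
      - {f_mech: [C], f_pos: [after], gr_mech: [A], gr_pos: [after], rel: [same-step]}
    text: "H of 1/Amin > H of 1/Amax"
  - id: 16
    when: {h_recip_amin_vs_amax: "="}
    predictions:
      - {f_mech: [A], f_pos: [after], gr_mech: [D], gr_pos: [before, at], rel: any}
    text: "H of 1/Amin = H of 1/Amax"
  - id: 17
    when: {ic50_dir: const}
    predictions:
      - {f_mech: [A], f_pos: [at], gr_mech: any, gr_pos: any, rel: any}
    text: "F is A at the CLS"
  - id: 18
    when: {ic50_dir: inc}
    predictions:
      - {f_mech: [L], f_pos: [before, at], gr_mech: [A], gr_pos: [after], rel: any}
      - {f_mech: [C], f_pos: any, gr_mech: [A], gr_pos: [after], rel: any}
      - {f_mech: [A], f_pos: [before], gr_mech: [C, L], gr_pos: [before], rel: any}
    text: "IC50 increases"
  - id: 19
    when: {ic50_dir: dec}
    predictions:
      - {f_mech: [A], f_pos: [before, after], gr_mech: [A], gr_pos: [after], rel: any}
      - {f_mech: [PU, PN], f_pos: [before], gr_mech: [A], gr_pos: [after], rel: any}
      - {f_mech: [C, L], f_pos: [before], gr_mech: [C, L], gr_pos: [before], rel: any}
    text: "IC50 decreases"
  - id: 20
    when: {ratio_dir: const}
    predictions:
      - {f_mech: any, f_pos: [before, at], gr_mech: any, gr_pos: any, rel: any}
      - {f_mech: any, f_pos: any, gr_mech: any, gr_pos: [before, at], rel: any}
    text: "Either F or GR acts before or at the CLS"
  - id: 21
    when: {ratio_dir: inc}
    predictions:
      - {f_mech: [C], f_pos: [after], gr_mech: [A], gr_pos: [after], rel: any}
      - {f_mech: [A], f_pos: [after], gr_mech: [D], gr_pos: [after], rel: any}
      - {f_mech: [D], f_pos: [after], gr_mech: [D], gr_pos: [after], rel: [GR-after-F]}
    text: "ratio increases"
  - id: 22
    when: {ratio_dir: dec}
    predictions:
      - {f_mech: [A], f_pos: [after], gr_mech: [A], gr_pos: [after], rel: any}
      - {f_mech: [A], f_pos: [after], gr_mech: [D], gr_pos: [after], rel: [GR-after-F]}
      - {f_mech: [D], f_pos: [after], gr_mech: [D], gr_pos: [after], rel: [GR-before-F]}
    text: "ratio decreases"
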