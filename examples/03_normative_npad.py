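"""Fit the GPR normative model and compare PAD, cPAD and nPAD bias.

The raw predicted-age difference (PAD) of any noisy predictor correlates
negatively with age (regression to the mean).  The normative model absorbs
that bias into the age/sex-specific peer mean, so nPAD — the z-score of a
person's predicted age among same-age same-sex peers — is bias-free, like
the linear cPAD correction but without assuming linearity.
"""

from scipy import stats

import brainpad as bp

config = bp.SyntheticConfig(seed=1)
gen = bp.CohortGenerator(config)
ref, fm = gen.reference()

model = bp.train_predictor(fm, ref, modality="GM", backend="ridge", seed=1)
pred = bp.predict_age(model, fm.select("GM"), ref["sex"])

normative = bp.fit_normative_gpr(pred, ref["age"], ref["sex"], seed=1)
pad = bp.score_pad(pred, ref["age"])
bias = bp.fit_bias_correction(pad, ref["age"])
scores = bp.compute_pad_scores(pred, ref, "GM", normative, bias)

for metric in ("pad", "cpad", "npad"):
    r, p = stats.pearsonr(scores[metric], ref["age"])
    print(f"corr({metric.upper():>4s}, age) = {r:+.3f}  (p = {p:.3g})")
print(f"\nreference nPAD: mean = {scores['npad'].mean():+.3f}, "
      f"SD = {scores['npad'].std():.3f}  (a z-score by construction)")

mean, sd, _ = bp.peer_moments(normative, [30.0, 60.0], [1, 1])
print(f"\npeer predicted age at (30, male): {mean[0]:.1f} +/- {sd[0]:.1f} y")
print(f"peer predicted age at (60, male): {mean[1]:.1f} +/- {sd[1]:.1f} y")
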