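"""Shared fixtures: a default synthetic study with fitted reference models.

The heavyweight pieces (reference cohort, ridge predictors, GPR normative
fits) are session-scoped so the many downstream tests reuse one instrument.
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import brainpad as bp


@dataclass
class Study:
    """A fitted reference instrument over the default synthetic world."""

    config: bp.SyntheticConfig
    generator: bp.CohortGenerator
    reference: pd.DataFrame
    features: bp.FeatureMatrix
    predictors: dict          # modality -> BrainAgePredictor (ridge backend)
    predicted: dict           # modality -> pd.Series over the reference
    normative: dict           # modality -> NormativeModel
    bias: dict                # modality -> BiasCorrectionFit

    def score_cohort(self, cohort, fm, modality):
        """Predict + nPAD/PAD/cPAD a cohort with the fitted instrument."""
        pred = bp.predict_age(self.predictors[modality], fm.select(modality),
                              cohort["sex"])
        return bp.compute_pad_scores(pred, cohort, modality,
                                     self.normative[modality],
                                     self.bias[modality])


@pytest.fixture(scope="session")
def study() -> Study:
    config = bp.SyntheticConfig(seed=1)
    gen = bp.CohortGenerator(config)
    ref, fm = gen.reference()
    predictors, predicted, normative, bias = {}, {}, {}, {}
    for modality in ("GM", "WM", "multimodal"):
        mdl = bp.train_predictor(fm, ref, modality, backend="ridge", seed=1)
        pred = bp.predict_age(mdl, fm.select(modality), ref["sex"])
        predictors[modality] = mdl
        predicted[modality] = pred
        normative[modality] = bp.fit_normative_gpr(pred, ref["age"], ref["sex"],
                                                   seed=1)
        bias[modality] = bp.fit_bias_correction(
            bp.score_pad(pred, ref["age"]), ref["age"])
    return Study(config=config, generator=gen, reference=ref, features=fm,
                 predictors=predictors, predicted=predicted,
                 normative=normative, bias=bias)


@pytest.fixture(scope="session")
def case_control_world(study):
    """Default case/control cohorts plus pooled demographics and scores."""
    (case, cfm), (control, kfm) = study.generator.case_control()
    demo = pd.concat([case[["age", "sex", "education", "group"]],
                      control[["age", "sex", "education", "group"]]])
    values = pd.concat([cfm.values, kfm.values]).loc[demo.index]
    fm = bp.FeatureMatrix(values, cfm.modality, cfm.interaction_features)
    npad = {}
    for modality in ("GM", "WM", "multimodal"):
        pred = bp.predict_age(study.predictors[modality], fm.select(modality),
                              demo["sex"])
        npad[modality] = pd.Series(
            bp.score_npad(study.normative[modality], pred, demo["age"],
                          demo["sex"]), index=demo.index)
    return {"case": case, "control": control, "demo": demo, "features": fm,
            "npad": pd.DataFrame(npad)}


def pooled_case_control(generator: bp.CohortGenerator, draw: int):
    """Redraw case/control under the same feature model; pooled tables."""
    (case, cfm), (control, kfm) = generator.case_control(draw=draw)
    demo = pd.concat([case[["age", "sex", "education", "group"]],
                      control[["age", "sex", "education", "group"]]])
    values = pd.concat([cfm.values, kfm.values]).loc[demo.index]
    fm = bp.FeatureMatrix(values, cfm.modality, cfm.interaction_features)
    return case, control, demo, fm


def npad_for(study, demo, fm, modality) -> pd.Series:
    pred = bp.predict_age(study.predictors[modality], fm.select(modality),
                          demo["sex"])
    return pd.Series(bp.score_npad(study.normative[modality], pred,
                                   demo["age"], demo["sex"]), index=demo.index)
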