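"""Synthetic ROI-feature cohorts with known ground truth.

Generates reference (normative training), independent test, and case/control
cohorts of regional gray-matter (volume, cortical thickness) and white-matter
(GFA, MD) features whose trajectories follow a simple aging law::

    value_ij = mu_j + beta_j * age_i + kappa_j * age_i**2 + gamma_j * sex_i + eps_ij

with ``eps_ij ~ Normal(0, sigma_j**2)``.  Aging directions follow the field's
conventions: volume, thickness and GFA decline with age (``beta_j <= 0``),
mean diffusivity rises (``beta_j >= 0``).  A configurable fraction of features
carries no age signal at all.

Cases receive a latent advanced-aging shift ``Delta_i ~ Normal(delta, omega**2)``
(in years) applied by evaluating the aging law at ``age_i + Delta_i``; a small
set of planted "interaction" features additionally responds to the shift with
amplified gain, ``value += interaction_slope_delta * beta_j * Delta_i``, so
that only those features co-vary with the shift beyond the global aging law.
Case phenotypes (PANSS scores, FSIQ, onset age, illness duration, antipsychotic
dose) are drawn with configurable coupling between the latent shift and the
negative-symptom / FSIQ scores, giving downstream regressions a recoverable
target.

Everything is deterministic given ``SyntheticConfig.seed``: each cohort draws
from its own child of a single :class:`numpy.random.SeedSequence`, so e.g. the
case/control draw does not perturb the reference draw.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, SchemaError

__all__ = [
    "SyntheticConfig",
    "FeatureMatrix",
    "CohortGenerator",
    "generate_reference_cohort",
    "generate_test_cohort",
    "generate_case_control_cohorts",
    "GM_MODALITIES",
    "WM_MODALITIES",
]

#: modality tags making up each model family
GM_MODALITIES = ("volume", "thickness")
WM_MODALITIES = ("gfa", "md")
ALL_MODALITIES = GM_MODALITIES + WM_MODALITIES

# Per-block generative scales.  Units loosely mimic real data (volumes in mL,
# thickness in mm, GFA dimensionless, MD in mm^2/s) purely so that I/O looks
# realistic; downstream methods never rely on the absolute scale.
_BLOCK_LAWS = {
    "volume": dict(mu=(3.0, 15.0), beta=(0.005, 0.013), sign=-1.0,
                   kappa=(0.0, 5e-5), gamma_mean=0.5, gamma_sd=0.2),
    "thickness": dict(mu=(2.0, 3.4), beta=(0.002, 0.0045), sign=-1.0,
                      kappa=(0.0, 2e-5), gamma_mean=0.0, gamma_sd=0.04),
    "gfa": dict(mu=(0.35, 0.65), beta=(0.0005, 0.0011), sign=-1.0,
                kappa=(0.0, 6e-6), gamma_mean=0.0, gamma_sd=0.008),
    "md": dict(mu=(6.5e-4, 9.5e-4), beta=(1.0e-6, 2.0e-6), sign=1.0,
               kappa=(0.0, 8e-9), gamma_mean=0.0, gamma_sd=8e-6),
}

_DEFAULT_NOISE_SD = {"volume": 0.7, "thickness": 0.25, "gfa": 0.04, "md": 5e-5}

# Case phenotype distributions (means, SDs) used as defaults.
_PHENOTYPE_LAWS = {
    "onset_age": (23.4, 6.9),
    "dose": (312.8, 269.8),
    "panss_pos": (13.1, 5.1),
    "panss_neg": (15.8, 7.2),
    "panss_gen": (28.2, 8.4),
    "fsiq": (93.8, 12.9),
}

PHENOTYPE_FIELDS = ("onset_age", "duration", "dose",
                    "panss_pos", "panss_neg", "panss_gen", "fsiq")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohorts.

    Defaults mirror the cohort shapes the package is designed around:
    a normative reference of 482 adults spanning ages 14-92, an independent
    test set of 70, and a case/control pair of 147/130 aged 16-62.
    """

    n_reference: int = 482
    n_test: int = 70
    n_case: int = 147
    n_control: int = 130
    age_range: tuple[float, float] = (14.0, 92.0)
    #: age range for the case/control cohorts (clinical sample is younger)
    case_age_range: tuple[float, float] = (16.0, 62.0)
    case_age_mean: float = 31.0
    case_age_sd: float = 8.4
    #: proportion of males (sex coded 1 = male, 0 = female)
    sex_ratio: float = 0.47
    n_features_per_block: Mapping[str, int] = field(
        default_factory=lambda: {"volume": 56, "thickness": 68, "gfa": 45, "md": 45})
    #: fraction of features per block carrying a nonzero age slope
    aging_signal_strength: float = 0.8
    #: per-block residual SD in feature units
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    #: mean advanced-aging shift delta of cases, years
    case_offset_years: float = 5.0
    #: SD of the per-subject shift Delta_i, years
    case_offset_sd: float = 3.0
    #: number of features given an amplified response to the case shift
    n_interaction_features: int = 10
    #: block the planted interaction features are drawn from
    interaction_block: str = "thickness"
    #: extra gain on the shift for planted features, as a multiple of beta_j;
    #: the default puts the planted interaction effects at Cohen's f2 ~ 0.08
    interaction_slope_delta: float = 20.0
    #: target correlations of phenotypes with the standardized latent shift
    phenotype_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"panss_neg": 0.5, "fsiq": -0.4})
    #: education mean/SD per group (controls/reference higher, per field norms)
    education_case: tuple[float, float] = (14.3, 2.5)
    education_normal: tuple[float, float] = (15.9, 1.2)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_reference", "n_test", "n_case", "n_control"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in ("age_range", "case_age_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name} must satisfy min < max")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.aging_signal_strength <= 1.0:
            raise ConfigurationError("aging_signal_strength must lie in [0, 1]")
        for block in ALL_MODALITIES:
            if block not in self.n_features_per_block:
                raise ConfigurationError(f"n_features_per_block missing block '{block}'")
            if int(self.n_features_per_block[block]) <= 0:
                raise ConfigurationError(f"n_features_per_block[{block}] must be positive")
            if self.noise_sd.get(block, 0.0) < 0.0:
                raise ConfigurationError(f"noise_sd[{block}] must be non-negative")
        if self.interaction_block not in ALL_MODALITIES:
            raise ConfigurationError(
                f"interaction_block must be one of {ALL_MODALITIES}")
        if self.n_interaction_features < 0:
            raise ConfigurationError("n_interaction_features must be non-negative")
        n_block = int(self.n_features_per_block[self.interaction_block])
        if self.n_interaction_features > n_block:
            raise ConfigurationError(
                "n_interaction_features exceeds the size of block "
                f"'{self.interaction_block}' ({n_block})")
        if self.case_offset_sd < 0.0:
            raise ConfigurationError("case_offset_sd must be non-negative")
        for key, rho in self.phenotype_coupling.items():
            if not -1.0 < rho < 1.0:
                raise ConfigurationError(
                    f"phenotype_coupling[{key}] must lie in (-1, 1)")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_features_per_block"] = dict(d["n_features_per_block"])
        d["noise_sd"] = dict(d["noise_sd"])
        d["phenotype_coupling"] = dict(d["phenotype_coupling"])
        return d


@dataclass
class FeatureMatrix:
    """Subjects x ROI features with per-feature modality metadata.

    ``values`` is indexed by subject id with one column per feature;
    ``modality`` maps each feature name to its block tag.  For synthetic
    cohorts, ``interaction_features`` records the planted ground truth.
    """

    values: pd.DataFrame
    modality: pd.Series
    interaction_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique:
            raise SchemaError("feature names must be unique")
        if list(self.modality.index) != list(self.values.columns):
            raise SchemaError("modality tags must cover exactly the feature columns")
        bad = set(self.modality) - set(ALL_MODALITIES)
        if bad:
            raise SchemaError(f"unknown modality tags: {sorted(bad)}")

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def select(self, which: str) -> "FeatureMatrix":
        """Restrict to a model family: ``"GM"``, ``"WM"`` or ``"multimodal"``."""
        which_tags = {"GM": GM_MODALITIES, "WM": WM_MODALITIES,
                      "multimodal": ALL_MODALITIES}.get(which)
        if which_tags is None:
            raise SchemaError(f"unknown modality selection '{which}' "
                              "(expected GM, WM or multimodal)")
        keep = [c for c in self.values.columns if self.modality[c] in which_tags]
        return FeatureMatrix(self.values[keep], self.modality[keep],
                             tuple(f for f in self.interaction_features if f in keep))

    def align_to(self, cohort: pd.DataFrame) -> "FeatureMatrix":
        """Reorder rows to a cohort table's subject order."""
        missing = cohort.index.difference(self.values.index)
        if len(missing):
            raise SchemaError(f"feature matrix missing subjects: {list(missing[:5])}")
        return FeatureMatrix(self.values.loc[cohort.index], self.modality,
                             self.interaction_features)


class _FeatureModel:
    """Per-feature generative parameters shared across cohorts."""

    def __init__(self, config: SyntheticConfig, rng: np.random.Generator):
        names, tags = [], []
        mu, beta, kappa, gamma, sigma = [], [], [], [], []
        prefix = {"volume": "vol", "thickness": "ct", "gfa": "gfa", "md": "md"}
        for block in ALL_MODALITIES:
            law = _BLOCK_LAWS[block]
            p = int(config.n_features_per_block[block])
            names += [f"{prefix[block]}_{i + 1:03d}" for i in range(p)]
            tags += [block] * p
            mu.append(rng.uniform(*law["mu"], size=p))
            has_signal = rng.random(p) < config.aging_signal_strength
            b = law["sign"] * rng.uniform(*law["beta"], size=p) * has_signal
            k = law["sign"] * rng.uniform(*law["kappa"], size=p) * has_signal
            beta.append(b)
            kappa.append(k)
            gamma.append(rng.normal(law["gamma_mean"], law["gamma_sd"], size=p))
            sigma.append(np.full(p, float(config.noise_sd[block])))
        self.names = names
        self.modality = pd.Series(tags, index=names, name="modality")
        self.mu = np.concatenate(mu)
        self.beta = np.concatenate(beta)
        self.kappa = np.concatenate(kappa)
        self.gamma = np.concatenate(gamma)
        self.sigma = np.concatenate(sigma)
        # planted interaction features: signal-carrying members of one block
        block_idx = np.flatnonzero(
            (self.modality.to_numpy() == config.interaction_block) & (self.beta != 0.0))
        n_int = min(config.n_interaction_features, block_idx.size)
        self.interaction_idx = np.sort(rng.choice(block_idx, size=n_int, replace=False))
        self.config = config

    @property
    def interaction_names(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.names)[self.interaction_idx])

    def noise_free(self, age_eff: np.ndarray, sex: np.ndarray) -> np.ndarray:
        """Evaluate the aging law (no residual) at effective ages."""
        a = np.asarray(age_eff, float)[:, None]
        s = np.asarray(sex, float)[:, None]
        return self.mu + self.beta * a + self.kappa * a ** 2 + self.gamma * s

    def sample(self, age: np.ndarray, sex: np.ndarray, rng: np.random.Generator,
               delta: np.ndarray | None = None) -> np.ndarray:
        age_eff = np.asarray(age, float)
        if delta is not None:
            age_eff = age_eff + delta
        vals = self.noise_free(age_eff, sex)
        if delta is not None and self.interaction_idx.size:
            ii = self.interaction_idx
            gain = self.config.interaction_slope_delta * self.beta[ii]
            vals[:, ii] += gain * np.asarray(delta, float)[:, None]
        noisy = np.any(self.sigma > 0)
        if noisy:
            vals = vals + rng.normal(0.0, self.sigma, size=vals.shape)
        return vals


def _truncnorm(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


class CohortGenerator:
    """Draws the feature model once, then generates cohorts on demand.

    Reference/test/control subjects follow the normative aging law; cases
    additionally carry the latent advanced-aging shift and phenotypes.
    """

    # stream constants keep each cohort's draw independent of the others
    _STREAMS = {"params": 0, "reference": 1, "test": 2, "control": 3, "case": 4}

    def __init__(self, config: SyntheticConfig):
        config.validate()
        self.config = config
        self.feature_model = _FeatureModel(config, self._rng("params"))

    def _rng(self, stream: str, draw: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.config.seed, self._STREAMS[stream], draw]))

    # -- cohorts ---------------------------------------------------------
    # ``draw`` redraws a cohort under the same feature model (generative
    # parameters stay fixed); draw=0 is the default cohort.

    def reference(self, draw: int = 0) -> tuple[pd.DataFrame, FeatureMatrix]:
        return self._normal_cohort(self._rng("reference", draw),
                                   self.config.n_reference, "reference", "ref")

    def test(self, draw: int = 0) -> tuple[pd.DataFrame, FeatureMatrix]:
        return self._normal_cohort(self._rng("test", draw),
                                   self.config.n_test, "test", "tst")

    def control(self, draw: int = 0) -> tuple[pd.DataFrame, FeatureMatrix]:
        return self._clinical_age_cohort(self._rng("control", draw),
                                         self.config.n_control, "control", "ctl")

    def case(self, draw: int = 0) -> tuple[pd.DataFrame, FeatureMatrix]:
        cfg = self.config
        rng = self._rng("case", draw)
        n = cfg.n_case
        age = _truncnorm(cfg.case_age_mean, cfg.case_age_sd,
                         *cfg.case_age_range, n, rng)
        sex = (rng.random(n) < cfg.sex_ratio).astype(int)
        edu = np.clip(rng.normal(*cfg.education_case, size=n), 6.0, 22.0)
        delta = rng.normal(cfg.case_offset_years, cfg.case_offset_sd, size=n)
        values = self.feature_model.sample(age, sex, rng, delta=delta)
        ids = [f"cas_{i + 1:04d}" for i in range(n)]
        cohort = pd.DataFrame({"age": age, "sex": sex, "education": edu,
                               "group": "case"}, index=pd.Index(ids, name="subject_id"))
        self._add_phenotypes(cohort, delta, rng)
        cohort["truth_delta_age"] = delta
        fm = FeatureMatrix(
            pd.DataFrame(values, index=cohort.index, columns=self.feature_model.names),
            self.feature_model.modality.copy(),
            self.feature_model.interaction_names)
        return cohort, fm

    def case_control(self, draw: int = 0):
        return self.case(draw), self.control(draw)

    # -- internals -------------------------------------------------------

    def _normal_cohort(self, rng, n, group, prefix):
        cfg = self.config
        age = rng.uniform(*cfg.age_range, size=n)
        sex = (rng.random(n) < cfg.sex_ratio).astype(int)
        edu = np.clip(rng.normal(*cfg.education_normal, size=n), 6.0, 22.0)
        values = self.feature_model.sample(age, sex, rng)
        ids = [f"{prefix}_{i + 1:04d}" for i in range(n)]
        cohort = pd.DataFrame({"age": age, "sex": sex, "education": edu,
                               "group": group}, index=pd.Index(ids, name="subject_id"))
        fm = FeatureMatrix(
            pd.DataFrame(values, index=cohort.index, columns=self.feature_model.names),
            self.feature_model.modality.copy(),
            self.feature_model.interaction_names)
        return cohort, fm

    def _clinical_age_cohort(self, rng, n, group, prefix):
        cfg = self.config
        age = _truncnorm(cfg.case_age_mean, cfg.case_age_sd,
                         *cfg.case_age_range, n, rng)
        sex = (rng.random(n) < cfg.sex_ratio).astype(int)
        edu = np.clip(rng.normal(*cfg.education_normal, size=n), 6.0, 22.0)
        values = self.feature_model.sample(age, sex, rng)
        ids = [f"{prefix}_{i + 1:04d}" for i in range(n)]
        cohort = pd.DataFrame({"age": age, "sex": sex, "education": edu,
                               "group": group}, index=pd.Index(ids, name="subject_id"))
        fm = FeatureMatrix(
            pd.DataFrame(values, index=cohort.index, columns=self.feature_model.names),
            self.feature_model.modality.copy(),
            self.feature_model.interaction_names)
        return cohort, fm

    def _add_phenotypes(self, cohort: pd.DataFrame, delta: np.ndarray,
                        rng: np.random.Generator) -> None:
        cfg = self.config
        n = len(cohort)
        sd = cfg.case_offset_sd
        z_delta = (delta - cfg.case_offset_years) / sd if sd > 0 else np.zeros(n)

        def coupled(key):
            mean, scale = _PHENOTYPE_LAWS[key]
            rho = float(cfg.phenotype_coupling.get(key, 0.0))
            z = rho * z_delta + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
            return mean, scale, z

        # negative symptoms load on the latent shift; positive/general share a
        # moderate symptom factor with them for realism
        m, s, z_neg = coupled("panss_neg")
        panss_neg = np.clip(m + s * z_neg, 7, 49)
        for key, out in (("panss_pos", "panss_pos"), ("panss_gen", "panss_gen")):
            mean, scale = _PHENOTYPE_LAWS[key]
            z = 0.3 * z_neg + np.sqrt(1 - 0.3 ** 2) * rng.standard_normal(n)
            lo, hi = (7, 49) if key == "panss_pos" else (16, 112)
            cohort[out] = np.clip(mean + scale * z, lo, hi)
        cohort["panss_neg"] = panss_neg

        m, s, z_fsiq = coupled("fsiq")
        cohort["fsiq"] = np.clip(m + s * z_fsiq, 40, 160)

        age = cohort["age"].to_numpy()
        onset_hi = np.maximum(age - 1.0, 13.0)
        m, s = _PHENOTYPE_LAWS["onset_age"]
        onset = np.minimum(_truncnorm(m, s, 12.0, 60.0, n, rng), onset_hi)
        cohort["onset_age"] = onset
        cohort["duration"] = age - onset
        m, s = _PHENOTYPE_LAWS["dose"]
        cohort["dose"] = _truncnorm(m, s, 25.0, 2000.0, n, rng)


# -- functional surface ---------------------------------------------------

def generate_reference_cohort(config: SyntheticConfig):
    """Reference (normative training) cohort: demographics + features."""
    return CohortGenerator(config).reference()


def generate_test_cohort(config: SyntheticConfig):
    """Independent normal test cohort drawn from the reference law."""
    return CohortGenerator(config).test()


def generate_case_control_cohorts(config: SyntheticConfig,
                                  generator: CohortGenerator | None = None):
    """Case and control cohorts sharing the reference feature model.

    Returns ``((case_cohort, case_features), (control_cohort, control_features))``.
    Case tables carry a ``truth_delta_age`` column with the latent shift and
    the feature matrices record the planted interaction features.
    """
    gen = generator if generator is not None else CohortGenerator(config)
    if generator is not None and generator.config != config:
        raise ConfigurationError("generator was built from a different config")
    return gen.case_control()


def truth_sidecar(generator: CohortGenerator) -> dict:
    """JSON-serializable ground-truth metadata for a synthetic run."""
    fm = generator.feature_model
    return {
        "interaction_features": list(fm.interaction_names),
        "case_offset_years": generator.config.case_offset_years,
        "case_offset_sd": generator.config.case_offset_sd,
        "aging_slopes": {n: float(b) for n, b in zip(fm.names, fm.beta)},
        "config": generator.config.to_dict(),
    }


def write_truth_json(generator: CohortGenerator, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_sidecar(generator), fh, indent=1)
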