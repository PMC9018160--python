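"""Reading and writing the package's delimited-text artifacts.

Dialect: comma-separated UTF-8 with a header row, '.' decimal, empty cells
for missing values; sex coded 1 = male, 0 = female; ages in decimal years.
Feature tables carry subject ids in the first column; per-feature modality
tags live in a companion ``*_meta.csv`` (feature, modality).  Run manifests
are deterministic JSON (no timestamps) so reruns can be compared byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError
from .synthetic import FeatureMatrix, SyntheticConfig

__all__ = [
    "read_cohort", "write_cohort", "read_features", "write_features",
    "load_run_config", "RunConfig", "write_manifest", "ensure_writable",
]

_FLOAT_FMT = "%.10g"


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, float_format=_FLOAT_FMT)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    for col in ("age", "sex"):
        if col not in df.columns:
            raise SchemaError(f"cohort table {path} lacks required column '{col}'")
    if not df.index.is_unique:
        raise SchemaError(f"cohort table {path} has duplicate subject ids")
    return df


def write_features(fm: FeatureMatrix, path) -> None:
    path = Path(path)
    fm.values.to_csv(path, float_format=_FLOAT_FMT)
    meta = pd.DataFrame({"feature": fm.feature_names,
                         "modality": [fm.modality[f] for f in fm.feature_names]})
    meta.to_csv(path.with_name(path.stem + "_meta.csv"), index=False)


def read_features(path) -> FeatureMatrix:
    path = Path(path)
    values = pd.read_csv(path, index_col=0)
    values.index.name = "subject_id"
    meta_path = path.with_name(path.stem + "_meta.csv")
    if not meta_path.exists():
        raise SchemaError(f"feature metadata file not found: {meta_path}")
    meta = pd.read_csv(meta_path)
    modality = pd.Series(meta["modality"].to_numpy(), index=meta["feature"])
    return FeatureMatrix(values, modality.loc[values.columns])


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    outdir: str = "brainpad_run"
    seed: int = 0
    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    modalities: tuple[str, ...] = ("GM", "WM", "multimodal")
    backend: str = "cascade"
    model_hyperparams: dict = dataclasses.field(default_factory=dict)
    kernel_opts: dict = dataclasses.field(default_factory=dict)
    cv_folds: int = 10
    outlier_threshold_sd: float = 3.0
    outlier_fields: tuple[str, ...] = ("onset_age", "duration", "dose",
                                       "panss_pos", "panss_neg", "panss_gen",
                                       "fsiq")
    bh_policy: str = "per_class"
    interaction_scans: tuple[str, ...] = ("GM", "WM")
    force: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") \
                else json.load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(syn, dict):
            syn_known = {f.name for f in dataclasses.fields(SyntheticConfig)}
            bad = set(syn) - syn_known
            if bad:
                raise ConfigurationError(f"unknown synthetic config keys: {sorted(bad)}")
            for tup in ("age_range", "case_age_range"):
                if tup in syn:
                    syn[tup] = tuple(syn[tup])
            syn = SyntheticConfig(**syn)
        for tup in ("modalities", "outlier_fields", "interaction_scans"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        cfg = cls(synthetic=syn, **raw)
        cfg.synthetic.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        for tup in ("modalities", "outlier_fields", "interaction_scans"):
            d[tup] = list(d[tup])
        return d

    def canonical_dict(self) -> dict:
        """Config content that determines outputs; execution-only options
        (force, log_level) are excluded so reruns hash identically."""
        d = self.to_dict()
        d.pop("force", None)
        d.pop("log_level", None)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_run_config(path_or_dict) -> RunConfig:
    if isinstance(path_or_dict, RunConfig):
        return path_or_dict
    if isinstance(path_or_dict, dict):
        return RunConfig.from_dict(path_or_dict)
    return RunConfig.from_file(path_or_dict)


def ensure_writable(path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise ConfigurationError(
            f"output {path} exists; pass force=True / --force to overwrite")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, stage: str, config: RunConfig,
                   inputs: list[str], outputs: list[str]) -> Path:
    """Deterministic per-stage manifest: config hash, seed, file checksums."""
    import brainpad
    outdir = Path(outdir)
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.canonical_dict(),
        "package_version": brainpad.__version__,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
    }
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
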