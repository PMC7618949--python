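"""Pipeline orchestration, configuration and file I/O.

Ties the stages together: synthetic cohort (or externally supplied HDF5 +
CSV) -> parcel preprocessing -> Welch PSD -> band powers -> spectral
parameterisation -> AEC connectivity -> metric table -> permutation GLM ->
result tables and a run manifest.

File formats: HDF5 for time courses / cached PSDs / AEC matrices, CSV for
covariates and the metric table, TSV for statistics, JSON for the ground
truth and manifest, YAML for configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BANDS, CANONICAL_BANDS, PEAK_BANDS
from .connectivity import aec_matrix, global_connectivity
from .glm import build_design, maxt_permutation
from .preprocess import clean_timecourses
from .spectral import PowerSpectrum, band_power, welch_psd
from .specparam import centre_of_energy, count_missing_peaks, fit_cohort, impute_missing_peaks, peak_table
from .synth import ParcelTimecourseSet

__all__ = [
    "PipelineConfig",
    "AnalysisConfig",
    "RunManifest",
    "read_cohort",
    "run_pipeline",
    "compute_metrics",
    "run_glm",
    "write_metrics",
]

_METRIC_FAMILIES = {
    "power": [b.name for b in CANONICAL_BANDS],
    "aec": [f"aec_{b.name}" for b in CANONICAL_BANDS],
    "exponent": ["exponent"],
    "coe": ["coe"],
    "alpha_peak_freq": ["alpha_peak_freq"],
    "alpha_peak_power": ["alpha_peak_power"],
    "beta_peak_freq": ["beta_peak_freq"],
    "beta_peak_power": ["beta_peak_power"],
}


@dataclass
class AnalysisConfig:
    name: str
    design: str  # ageing | group_compare | beta_ageing_by_group
    groups: list[str] | None = None  # subset of cohort groups; None = all
    metrics: list[str] = field(default_factory=lambda: ["power", "exponent", "coe", "aec"])

    def validate(self) -> None:
        if self.design not in ("ageing", "group_compare", "beta_ageing_by_group"):
            raise ValueError(f"unknown design {self.design!r}")
        unknown = [m for m in self.metrics if m not in _METRIC_FAMILIES]
        if unknown:
            raise ValueError(f"unknown metric families {unknown}; known: {sorted(_METRIC_FAMILIES)}")


@dataclass
class PipelineConfig:
    data_h5: str = "cohort.h5"
    covariates_csv: str = "covariates.csv"
    out_dir: str = "out"
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {b.name: (b.lo, b.hi) for b in CANONICAL_BANDS}
    )
    bandpass: tuple[float, float] = (1.0, 80.0)
    bad_segment_window_s: float = 1.0
    bad_segment_z: float = 3.0
    welch_window_s: float = 2.0
    specparam_range: tuple[float, float] = (1.0, 70.0)
    aec_trim_s: float = 1.0
    analyses: list[AnalysisConfig] = field(
        default_factory=lambda: [AnalysisConfig("group_compare", "group_compare")]
    )
    n_perm: int = 5000
    seed: int = 0

    def validate(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if name not in BANDS:
                raise ValueError(f"unknown band name {name!r}; known: {sorted(BANDS)}")
            if (lo, hi) != (BANDS[name].lo, BANDS[name].hi):
                raise ValueError(f"band {name} edges {lo}-{hi} differ from canonical")
        for a in self.analyses:
            a.validate()
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        analyses = [AnalysisConfig(**a) for a in raw.pop("analyses", [])] or None
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        if analyses is not None:
            cfg.analyses = analyses
        cfg.bands = {k: tuple(v) for k, v in cfg.bands.items()}
        cfg.bandpass = tuple(cfg.bandpass)
        cfg.specparam_range = tuple(cfg.specparam_range)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "analyses"
        }
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        d["bandpass"] = list(self.bandpass)
        d["specparam_range"] = list(self.specparam_range)
        d["analyses"] = [
            {"name": a.name, "design": a.design, "groups": a.groups, "metrics": a.metrics}
            for a in self.analyses
        ]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict[str, float] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_cohort(h5_path, csv_path) -> tuple[list[ParcelTimecourseSet], pd.DataFrame]:
    """Load the HDF5 + CSV cohort layout written by the simulator.

    Validates that every subject in the covariate table has data, that the
    sampling-rate attribute is present, that parcel labels match the matrix
    rows, and that no covariate is missing.
    """
    records = pd.read_csv(csv_path)
    required = ["subject_id", "group", "age", "sex", "scanner", "gm_volume"]
    missing_cols = [c for c in required if c not in records.columns]
    if missing_cols:
        raise ValueError(f"covariate CSV missing columns {missing_cols}")
    na_rows = records.index[records[required].isna().any(axis=1)].tolist()
    if na_rows:
        raise ValueError(f"covariate CSV has missing values in rows {na_rows}")

    subjects = []
    with h5py.File(h5_path, "r") as h5:
        available = set(h5["subjects"].keys()) if "subjects" in h5 else set()
        for sid in records["subject_id"]:
            if sid not in available:
                raise ValueError(f"subject {sid!r} present in CSV but absent from HDF5")
            dset = h5[f"subjects/{sid}/timecourses"]
            if "fs" not in dset.attrs:
                raise ValueError(f"subject {sid!r}: sampling-rate attribute missing")
            labels = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in dset.attrs.get("parcel_labels", [])
            ]
            data = dset[()]
            if labels and len(labels) != data.shape[0]:
                raise ValueError(f"subject {sid!r}: parcel-label count != matrix rows")
            subjects.append(
                ParcelTimecourseSet(
                    subject_id=sid,
                    data=data,
                    fs=float(dset.attrs["fs"]),
                    parcel_labels=labels or [f"parcel-{p:02d}" for p in range(data.shape[0])],
                )
            )
    return subjects, records


def compute_metrics(
    subjects: list[ParcelTimecourseSet], config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(subject, parcel) metric table plus per-subject missing-peak counts.

    Columns: the six band powers, exponent, coe, alpha/beta peak frequency
    and power (cohort-mean imputed where no peak was detected, with flags)
    and global AEC per band.
    """
    rows = []
    fits_by_subject = {}
    for subject in subjects:
        clean, _mask = clean_timecourses(
            subject.data,
            subject.fs,
            lo=config.bandpass[0],
            hi=config.bandpass[1],
            window_s=config.bad_segment_window_s,
            z_thresh=config.bad_segment_z,
        )
        psd = welch_psd(clean, subject.fs, window_s=config.welch_window_s)
        fits = fit_cohort(psd, f_range=config.specparam_range)
        fits_by_subject[subject.subject_id] = fits

        aec = {}
        for band in CANONICAL_BANDS:
            g = global_connectivity(
                aec_matrix(clean, subject.fs, band, trim_s=config.aec_trim_s)
            )
            aec[band.name] = g.values

        for p in range(psd.n_parcels):
            row = {"subject_id": subject.subject_id, "parcel": p}
            for band in CANONICAL_BANDS:
                row[band.name] = float(
                    band_power(PowerSpectrum(psd.freqs, psd.density[p : p + 1]), band)
                )
            row["exponent"] = fits[p].exponent
            row["coe"] = centre_of_energy(fits[p])
            for band in CANONICAL_BANDS:
                row[f"aec_{band.name}"] = float(aec[band.name][p])
            rows.append(row)

    metrics = pd.DataFrame(rows)

    peaks = peak_table(fits_by_subject, PEAK_BANDS)
    missing = count_missing_peaks(peaks).reset_index()
    imputed = impute_missing_peaks(peaks)
    wide = imputed.pivot(index=["subject_id", "parcel"], columns="band")
    for band_name in PEAK_BANDS:
        for col, new in (
            ("peak_freq", f"{band_name}_peak_freq"),
            ("peak_power", f"{band_name}_peak_power"),
            ("imputed", f"{band_name}_peak_imputed"),
        ):
            metrics = metrics.merge(
                wide[col][band_name].rename(new).reset_index(),
                on=["subject_id", "parcel"],
                how="left",
            )
    return metrics, missing


def write_metrics(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, index=False, float_format="%.10g")


def _metric_matrix(metrics: pd.DataFrame, records: pd.DataFrame, families: list[str]):
    """Subjects x cells matrix for the requested metric families."""
    cols = [c for fam in families for c in _METRIC_FAMILIES[fam]]
    wide = metrics.pivot(index="subject_id", columns="parcel", values=cols)
    wide = wide.loc[records["subject_id"]]
    labels = [f"{metric}:parcel{parcel}" for metric, parcel in wide.columns]
    Y = wide.to_numpy(dtype=float)
    keep = ~np.isnan(Y).any(axis=0)
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} metric cells with missing values excluded from GLM",
            stacklevel=2,
        )
    return Y[:, keep], [l for l, k in zip(labels, keep) if k]


def run_glm(
    metrics: pd.DataFrame,
    records: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Run every configured analysis; one max-t family per metric family."""
    frames = []
    for analysis in config.analyses:
        recs = records
        if analysis.groups:
            recs = records[records["group"].isin(analysis.groups)].reset_index(drop=True)
        design, contrasts = build_design(recs, analysis.design)
        for fam in analysis.metrics:
            Y, labels = _metric_matrix(metrics, recs, [fam])
            for ci, contrast in enumerate(contrasts):
                res = maxt_permutation(
                    Y,
                    design,
                    contrast,
                    n_perm=config.n_perm,
                    seed=(config.seed * 10007 + ci) % 2**31,
                    cell_labels=labels,
                )
                frame = res.to_frame()
                frame.insert(0, "analysis", analysis.name)
                frame.insert(1, "family", fam)
                frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order and write outputs plus a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__, seed=config.seed
    )

    t0 = time.time()
    subjects, records = read_cohort(config.data_h5, config.covariates_csv)
    manifest.stages["read"] = time.time() - t0

    t0 = time.time()
    metrics, missing = compute_metrics(subjects, config)
    metrics_path = out / "metrics.csv"
    missing_path = out / "missing_peaks.csv"
    write_metrics(metrics, metrics_path)
    missing.to_csv(missing_path, index=False)
    manifest.stages["metrics"] = time.time() - t0

    t0 = time.time()
    results = run_glm(metrics, records, config)
    results_path = out / "glm_results.tsv"
    results.to_csv(results_path, sep="\t", index=False, float_format="%.10g")
    manifest.stages["glm"] = time.time() - t0

    for path in (metrics_path, missing_path, results_path):
        manifest.checksums[path.name] = _sha256_file(path)
    manifest.write(out / "manifest.json")
    return manifest


def summarise_results(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-contrast summary: significant cells at the FWE threshold."""
    sig = results[results["p_fwe"] < alpha].copy()
    return sig.sort_values(["analysis", "family", "contrast", "p_fwe"]).reset_index(drop=True)
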