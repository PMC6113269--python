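"""Synthetic two-group x two-phase resting-state cohort generator.

Emulates a case-control menstrual-cycle study: a primary-dysmenorrhea (PDM)
group and a control (CON) group, each scanned in the menstrual (MENS) and
periovulatory (POV) phases. Each subject-phase yields a T x N parcel
time-series matrix with

* block-modular latent correlation structure (``rho_within`` inside each
  planted module, ``rho_between`` across modules),
* temporal autocorrelation from a shared AR(1) filter applied per parcel,
* small-gain nuisance contamination (6 smooth "motion" random walks plus
  2 slow "WM/CSF" signals) so the cleaning stage has real work to do,

and a covariate draw (three gonadal hormones, four psychological scores)
from group x phase normal distributions truncated to instrument ranges.

The generator's defaults reproduce the reference cohort: 57 PDM and 62
control subjects, 200 samples at TR = 2.5 s over 90 parcels, five
near-equal planted modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .datatypes import ParcelTimeSeries, default_parcel_labels

Group = Literal["PDM", "CON"]
Phase = Literal["MENS", "POV"]

GROUPS: tuple[Group, Group] = ("PDM", "CON")
PHASES: tuple[Phase, Phase] = ("MENS", "POV")

COVARIATE_NAMES = (
    "estradiol",
    "progesterone",
    "testosterone",
    "state_anxiety",
    "trait_anxiety",
    "beck_anxiety",
    "beck_depression",
)

#: (mean, sd) per covariate per (group, phase); hormone units pg/mL
#: (estradiol) and ng/mL (progesterone, testosterone), questionnaires in
#: raw scores.
DEFAULT_COVARIATE_PARAMS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("PDM", "MENS"): {
        "estradiol": (35.4, 18.52),
        "progesterone": (0.5, 0.39),
        "testosterone": (0.4, 0.23),
        "state_anxiety": (43.1, 9.03),
        "trait_anxiety": (44.9, 8.87),
        "beck_anxiety": (12.0, 7.87),
        "beck_depression": (11.5, 7.92),
    },
    ("PDM", "POV"): {
        "estradiol": (157.9, 111.21),
        "progesterone": (0.9, 1.19),
        "testosterone": (0.6, 0.31),
        "state_anxiety": (36.5, 7.10),
        "trait_anxiety": (43.0, 8.40),
        "beck_anxiety": (6.4, 5.50),
        "beck_depression": (6.1, 6.31),
    },
    ("CON", "MENS"): {
        "estradiol": (43.3, 30.13),
        "progesterone": (1.0, 2.41),
        "testosterone": (0.4, 0.23),
        "state_anxiety": (34.1, 7.35),
        "trait_anxiety": (37.8, 7.23),
        "beck_anxiety": (2.4, 2.38),
        "beck_depression": (4.5, 4.89),
    },
    ("CON", "POV"): {
        "estradiol": (144.7, 121.66),
        "progesterone": (1.3, 2.83),
        "testosterone": (0.5, 0.22),
        "state_anxiety": (34.1, 7.68),
        "trait_anxiety": (37.8, 7.61),
        "beck_anxiety": (3.2, 3.37),
        "beck_depression": (4.3, 5.53),
    },
}

#: instrument ranges used for truncation: hormones have a floor of 0,
#: state/trait anxiety run 20-80, Beck inventories 0-63.
COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "estradiol": (0.0, np.inf),
    "progesterone": (0.0, np.inf),
    "testosterone": (0.0, np.inf),
    "state_anxiety": (20.0, 80.0),
    "trait_anxiety": (20.0, 80.0),
    "beck_anxiety": (0.0, 63.0),
    "beck_depression": (0.0, 63.0),
}


#: enrolled neuroimaging sample and head-motion exclusions (translation
#: > 2 mm or rotation > 2 degrees) behind the default group sizes
ENROLLED_SIZES = {"PDM": 59, "CON": 68}
MOTION_EXCLUDED = {"PDM": 2, "CON": 6}


def analyzed_group_sizes(
    enrolled: dict[str, int] | None = None,
    excluded: dict[str, int] | None = None,
) -> dict[str, int]:
    """Group sizes after head-motion exclusion; the defaults yield the
    57 PDM / 62 control analyzed sample."""
    enrolled = dict(ENROLLED_SIZES if enrolled is None else enrolled)
    excluded = dict(MOTION_EXCLUDED if excluded is None else excluded)
    out = {}
    for group, n in enrolled.items():
        n_out = n - excluded.get(group, 0)
        if n_out < 0:
            raise ValueError(f"more exclusions than enrolled in group {group}")
        out[group] = n_out
    return out


def near_equal_partition(n_parcels: int, n_modules: int) -> np.ndarray:
    """Module labels 1..K over parcels in K contiguous near-equal blocks."""
    if n_modules < 1 or n_modules > n_parcels:
        raise ValueError("need 1 <= n_modules <= n_parcels")
    sizes = np.full(n_modules, n_parcels // n_modules, dtype=int)
    sizes[: n_parcels % n_modules] += 1
    return np.repeat(np.arange(1, n_modules + 1), sizes)


@dataclass
class EffectSpec:
    """Additive shifts on the block correlations for selected cells.

    ``shifts`` maps (group, phase) to (delta_rho_within, delta_rho_between).
    Cells not listed are unshifted. Used to plant recoverable group or
    phase effects for power and recovery experiments.
    """

    shifts: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def applied(self, group: str, phase: str, rho_within: float, rho_between: float) -> tuple[float, float]:
        dw, db = self.shifts.get((group, phase), (0.0, 0.0))
        return rho_within + dw, rho_between + db


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_group1: int = 57  # PDM
    n_group2: int = 62  # CON
    n_parcels: int = 90
    n_samples: int = 200
    tr_seconds: float = 2.5
    n_modules: int = 5
    planted_partition: np.ndarray | None = None
    rho_within: float = 0.4
    rho_between: float = 0.1
    ar_coefficient: float = 0.3
    nuisance_gain: float = 0.2
    effect_spec: EffectSpec | None = None
    covariate_params: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_PARAMS.items()
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ValueError("group sizes must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least 2 time samples")
        if not (0 <= self.rho_between < self.rho_within < 1):
            raise ValueError(
                "require 0 <= rho_between < rho_within < 1, got "
                f"rho_within={self.rho_within}, rho_between={self.rho_between}"
            )
        if not (-1 < self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        if self.planted_partition is None:
            self.planted_partition = near_equal_partition(self.n_parcels, self.n_modules)
        self.planted_partition = np.asarray(self.planted_partition, dtype=int)
        if self.planted_partition.size != self.n_parcels:
            raise ValueError("planted partition must label every parcel")
        # fail fast if the implied block correlation is not positive definite
        _block_cholesky(self.planted_partition, self.rho_within, self.rho_between)

    @property
    def n_subjects(self) -> int:
        return self.n_group1 + self.n_group2

    @property
    def parcel_labels(self) -> list[str]:
        return default_parcel_labels(self.n_parcels)

    def to_json_dict(self) -> dict:
        d = {
            "n_group1": self.n_group1,
            "n_group2": self.n_group2,
            "n_parcels": self.n_parcels,
            "n_samples": self.n_samples,
            "tr_seconds": self.tr_seconds,
            "n_modules": self.n_modules,
            "planted_partition": self.planted_partition.tolist(),
            "rho_within": self.rho_within,
            "rho_between": self.rho_between,
            "ar_coefficient": self.ar_coefficient,
            "nuisance_gain": self.nuisance_gain,
            "effect_spec": (
                {f"{g}:{p}": list(v) for (g, p), v in self.effect_spec.shifts.items()}
                if self.effect_spec
                else None
            ),
            "seed": self.seed,
        }
        return d


@dataclass
class NuisanceSet:
    """Named nuisance regressors (T x K): motion parameters and slow
    white-matter / ventricular signals."""

    regressors: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be T x K")
        if self.regressors.shape[1] != len(self.names):
            raise ValueError("one name per regressor column required")


@dataclass
class SubjectRecord:
    """One subject-phase observation: series, covariates, nuisance truth."""

    subject_id: str
    group: Group
    phase: Phase
    covariates: dict[str, float]
    series: ParcelTimeSeries
    nuisance: NuisanceSet

    def __post_init__(self) -> None:
        if any(not np.isfinite(v) for v in self.covariates.values()):
            raise ValueError("covariates must be finite")


def _block_cholesky(partition: np.ndarray, rho_within: float, rho_between: float) -> np.ndarray:
    """Cholesky factor of the block-constant correlation matrix; raises a
    configuration error when the implied matrix is not positive definite."""
    same = partition[:, None] == partition[None, :]
    sigma = np.where(same, rho_within, rho_between)
    np.fill_diagonal(sigma, 1.0)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ValueError(
            "implied block correlation matrix is not positive definite "
            f"(rho_within={rho_within}, rho_between={rho_between})"
        ) from None


def _ar1_filter(x: np.ndarray, ar: float) -> np.ndarray:
    """Apply y[t] = ar*y[t-1] + x[t] down each column (shared filter, so
    cross-column correlations are preserved)."""
    if ar == 0.0:
        return x
    y = np.empty_like(x)
    y[0] = x[0]
    for t in range(1, x.shape[0]):
        y[t] = ar * y[t - 1] + x[t]
    return y


def _make_nuisance(t: int, tr: float, rng: np.random.Generator) -> NuisanceSet:
    """Six smooth random-walk motion traces plus two slow WM/CSF signals,
    each standardized to unit variance."""
    cols = []
    names = []
    for k, name in enumerate(("tx", "ty", "tz", "rx", "ry", "rz")):
        walk = np.cumsum(rng.normal(0.0, 1.0, size=t))
        # light smoothing so the walk looks like slow drift, not noise
        kernel = np.ones(5) / 5.0
        walk = np.convolve(walk, kernel, mode="same")
        cols.append(walk)
        names.append(f"motion_{name}")
    time = np.arange(t) * tr
    for name, freq in (("wm", 0.005), ("csf", 0.008)):
        phase = rng.uniform(0, 2 * np.pi)
        sig = np.sin(2 * np.pi * freq * time + phase) + 0.3 * rng.normal(size=t)
        cols.append(sig)
        names.append(f"{name}_signal")
    reg = np.column_stack(cols)
    reg = (reg - reg.mean(axis=0)) / reg.std(axis=0)
    return NuisanceSet(reg, names)


def generate_subject_timeseries(
    partition: np.ndarray,
    rho_within: float,
    rho_between: float,
    t: int,
    ar: float = 0.0,
    seed: int | np.random.Generator = 0,
    tr_seconds: float = 2.5,
    parcel_labels: list[str] | None = None,
) -> ParcelTimeSeries:
    """Draw a T x N series from the block-modular latent covariance with an
    AR(1) temporal filter.

    Columns have unit marginal variance in expectation before filtering;
    the AR filter is shared across columns, so the block correlation
    structure carries through unchanged.
    """
    if t < 2:
        raise ValueError("need at least 2 time samples")
    partition = np.asarray(partition, dtype=int)
    n = partition.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rho_within == 0.0 and rho_between == 0.0:
        latent = rng.standard_normal((t, n))
    else:
        if not (0 <= rho_between <= rho_within < 1):
            raise ValueError("correlations must satisfy 0 <= rho_between <= rho_within < 1")
        chol = _block_cholesky(partition, rho_within, rho_between)
        latent = rng.standard_normal((t, n)) @ chol.T
    values = _ar1_filter(latent, ar)
    if parcel_labels is None:
        parcel_labels = default_parcel_labels(n)
    return ParcelTimeSeries(values, parcel_labels, tr_seconds)


def generate_covariates(
    group: str,
    phase: str,
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """One covariate draw for a subject in the given group x phase cell.

    Values come from normal(mean, sd) clipped to instrument ranges
    (hormones floored at 0; questionnaires at their printed ranges).
    """
    key = (group, phase)
    if key not in config.covariate_params:
        raise KeyError(f"no covariate parameters for cell {key}")
    params = config.covariate_params[key]
    unknown = set(params) - set(COVARIATE_NAMES)
    if unknown:
        raise KeyError(f"unknown covariate name(s): {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for name in COVARIATE_NAMES:
        mean, sd = params[name]
        lo, hi = COVARIATE_RANGES[name]
        value = mean if sd == 0 else rng.normal(mean, sd)
        out[name] = float(np.clip(value, lo, hi))
    return out


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate the full cohort: two records (MENS, POV) per subject.

    Returns records ordered by subject then phase. Identical config and
    seed give bit-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    effect = config.effect_spec or EffectSpec()
    records: list[SubjectRecord] = []
    labels = config.parcel_labels
    group_sizes = {"PDM": config.n_group1, "CON": config.n_group2}
    n_streams_per_subject = 2 * 3  # per phase: series, nuisance, covariates
    children = ss.spawn(config.n_subjects * n_streams_per_subject)
    subject_index = 0
    for group in GROUPS:
        for k in range(group_sizes[group]):
            sid = f"{group}{k + 1:03d}"
            base = subject_index * n_streams_per_subject
            for p_idx, phase in enumerate(PHASES):
                rng_series = np.random.default_rng(children[base + 3 * p_idx])
                rng_nuis = np.random.default_rng(children[base + 3 * p_idx + 1])
                rng_cov = np.random.default_rng(children[base + 3 * p_idx + 2])
                rw, rb = effect.applied(group, phase, config.rho_within, config.rho_between)
                series = generate_subject_timeseries(
                    config.planted_partition,
                    rw,
                    rb,
                    config.n_samples,
                    ar=config.ar_coefficient,
                    seed=rng_series,
                    tr_seconds=config.tr_seconds,
                    parcel_labels=labels,
                )
                nuis = _make_nuisance(config.n_samples, config.tr_seconds, rng_nuis)
                if config.nuisance_gain > 0:
                    loadings = rng_nuis.normal(
                        0.0, config.nuisance_gain, size=(nuis.regressors.shape[1], config.n_parcels)
                    )
                    contaminated = series.values + nuis.regressors @ loadings
                    series = series.with_values(contaminated)
                cov = generate_covariates(group, phase, config, seed=rng_cov)
                records.append(
                    SubjectRecord(sid, group, phase, cov, series, nuis)
                )
            subject_index += 1
    return records


def write_cohort(records: list[SubjectRecord], outdir: str | Path, config: CohortConfig | None = None) -> Path:
    """Write one TSV matrix per subject-phase plus manifest and covariate
    tables; echo the config as JSON. Returns the manifest path."""
    from .io import write_matrix_tsv  # local import to avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    cov_rows = []
    for rec in records:
        fname = f"{rec.subject_id}_{rec.phase}.tsv"
        write_matrix_tsv(
            outdir / fname,
            rec.series.values,
            row_labels=[f"t{i}" for i in range(rec.series.n_samples)],
            col_labels=rec.series.parcel_labels,
        )
        nname = f"{rec.subject_id}_{rec.phase}_nuisance.tsv"
        write_matrix_tsv(
            outdir / nname,
            rec.nuisance.regressors,
            row_labels=[f"t{i}" for i in range(rec.nuisance.regressors.shape[0])],
            col_labels=rec.nuisance.names,
        )
        manifest_rows.append(
            "\t".join([rec.subject_id, rec.group, rec.phase, fname, nname])
        )
        cov_rows.append(
            "\t".join(
                [rec.subject_id, rec.group, rec.phase]
                + [repr(rec.covariates[c]) for c in COVARIATE_NAMES]
            )
        )
    manifest = outdir / "manifest.tsv"
    manifest.write_text(
        "subject_id\tgroup\tphase\tseries_path\tnuisance_path\n"
        + "\n".join(manifest_rows)
        + "\n"
    )
    (outdir / "covariates.tsv").write_text(
        "subject_id\tgroup\tphase\t" + "\t".join(COVARIATE_NAMES) + "\n"
        + "\n".join(cov_rows)
        + "\n"
    )
    if config is not None:
        (outdir / "config.json").write_text(json.dumps(config.to_json_dict(), indent=2))
    return manifest
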