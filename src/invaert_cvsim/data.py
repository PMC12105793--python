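"""Dataset generation for network training: priors, simulation batches,
splits, normalization, noise injection and synthetic EHR-style tables.

Training data are input-output pairs ``(v, y)`` obtained by running the
simulator on draws from a uniform box prior centred on the default parameter
set.  Two presets mirror the two studies the package supports: a *synthetic*
prior (compliances within +/-50%, everything else within +/-30% of default)
and a wider *ehr* prior (heart rate -20/+60%, compliances and resistances
-80/+60%, remaining parameters +/-30%) whose outputs cover most clinically
plausible measurements.

Measurement noise is modelled as zero-mean, uncorrelated, heteroskedastic
Gaussian noise ``y' = y + eta`` with per-component standard deviations from
the literature (``OUTPUT_STDS``), amplified by a scale factor ``delta``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cvsim6 import (
    OUTPUT_NAMES,
    OUTPUT_STDS,
    PARAM_NAMES,
    CVSimError,
    ParameterSet,
    SimulationConfig,
    default_parameters,
    extract_outputs,
    simulate,
)

logger = logging.getLogger(__name__)

#: Parameter groups used by the prior presets.
COMPLIANCE_PARAMS = ["Cl_dia", "Cl_sys", "Ca", "Cv", "Cr_dia", "Cr_sys",
                     "Cpa", "Cpv"]
RESISTANCE_PARAMS = ["Rl_in", "Rl_out", "Ra", "Rr_in", "Rr_out", "Rpv"]

#: Fast generation profile: LSODA with tolerances giving ~1e-4 relative
#: output accuracy versus the Radau reference at ~10x the speed.
GENERATION_CONFIG = SimulationConfig(solver="lsoda", rel_tol=1e-7,
                                     abs_tol=1e-3)


def _interval(ref: float, lo_frac: float, hi_frac: float) -> tuple[float, float]:
    """Multiplicative interval [ref*(1+lo), ref*(1+hi)], ordered even when
    the reference value is negative (e.g. the transthoracic pressure)."""
    a, b = ref * (1.0 + lo_frac), ref * (1.0 + hi_frac)
    return (min(a, b), max(a, b))


@dataclass
class PriorSpec:
    """Uniform box prior over the 23 parameters.

    ``bounds`` maps each parameter name to absolute (lower, upper) limits.
    Use :meth:`synthetic` or :meth:`ehr` for the two study presets.
    """

    bounds: dict[str, tuple[float, float]]
    preset: str = "custom"

    def __post_init__(self):
        missing = [n for n in PARAM_NAMES if n not in self.bounds]
        if missing:
            raise CVSimError(f"prior is missing bounds for {missing}")
        for n, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise CVSimError(f"prior bounds for {n} not ordered: "
                                 f"({lo}, {hi})")

    @classmethod
    def from_fractions(cls, fractions: dict[str, tuple[float, float]],
                       reference: ParameterSet | None = None,
                       preset: str = "custom") -> "PriorSpec":
        ref = reference or default_parameters()
        bounds = {n: _interval(getattr(ref, n), *fractions[n])
                  for n in PARAM_NAMES}
        return cls(bounds=bounds, preset=preset)

    @classmethod
    def synthetic(cls, reference: ParameterSet | None = None) -> "PriorSpec":
        """Structural-identifiability study: compliances +/-50%, all other
        parameters +/-30% around the default set."""
        fr = {n: (-0.5, 0.5) if n in COMPLIANCE_PARAMS else (-0.3, 0.3)
              for n in PARAM_NAMES}
        return cls.from_fractions(fr, reference, preset="synthetic")

    @classmethod
    def ehr(cls, reference: ParameterSet | None = None) -> "PriorSpec":
        """Clinical-cohort study: Hr -20/+60%, compliances and resistances
        -80/+60%, remaining parameters +/-30%."""
        fr = {}
        for n in PARAM_NAMES:
            if n == "Hr":
                fr[n] = (-0.2, 0.6)
            elif n in COMPLIANCE_PARAMS or n in RESISTANCE_PARAMS:
                fr[n] = (-0.8, 0.6)
            else:
                fr[n] = (-0.3, 0.3)
        return cls.from_fractions(fr, reference, preset="ehr")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAM_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAM_NAMES])

    def contains(self, V) -> np.ndarray:
        """Row-wise box membership for a (n, 23) batch."""
        V = np.atleast_2d(np.asarray(V, dtype=float))
        return np.all((V >= self.lower) & (V <= self.upper), axis=1)


def sample_prior(prior: PriorSpec, n: int, seed: int | np.random.Generator
                 ) -> np.ndarray:
    """``n`` i.i.d. uniform draws from the prior box, shape (n, 23)."""
    if n < 1:
        raise CVSimError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.uniform(prior.lower, prior.upper, size=(n, len(PARAM_NAMES)))


@dataclass
class NoiseModel:
    """Heteroskedastic Gaussian measurement noise in physical output units.

    ``s`` holds the 16 per-component standard deviations (defaults to the
    literature values); ``delta`` scales them globally, delta=0 meaning no
    corruption.
    """

    s: np.ndarray = field(default_factory=lambda: OUTPUT_STDS.copy())
    delta: float = 1.0

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (16,):
            raise CVSimError("noise model needs 16 standard deviations")
        if np.any(self.s < 0):
            raise CVSimError("standard deviations must be non-negative")
        if self.delta < 0:
            raise CVSimError(f"noise scale delta must be >= 0, "
                             f"got {self.delta}")


def inject_noise(Y, noise: NoiseModel, seed: int | np.random.Generator
                 ) -> np.ndarray:
    """Corrupt outputs (physical units) with ``y' = y + delta*s*eps``,
    eps ~ N(0, I), independently per entry.  Each call draws fresh noise;
    per-epoch semantics are owned by the trainer."""
    Y = np.asarray(Y, dtype=float)
    if noise.delta == 0.0:
        return Y.copy()
    rng = np.random.default_rng(seed)
    return Y + rng.standard_normal(Y.shape) * (noise.delta * noise.s)


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

SPLIT_TRAIN, SPLIT_TEST, SPLIT_VALID = "train", "test", "validation"

#: Reference full-scale split: 4000 offline validation out of 54000, the
#: remainder divided 3:1 into training and online testing.
FULL_SCALE_N = 54_000
FULL_SCALE_VALID = 4_000


@dataclass
class NormalizationStats:
    """Per-feature z-score statistics, estimated on the training split."""

    v_mean: np.ndarray
    v_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    def normalize_v(self, V):
        return (np.asarray(V, dtype=float) - self.v_mean) / self.v_std

    def denormalize_v(self, V):
        return np.asarray(V, dtype=float) * self.v_std + self.v_mean

    def normalize_y(self, Y):
        return (np.asarray(Y, dtype=float) - self.y_mean) / self.y_std

    def denormalize_y(self, Y):
        return np.asarray(Y, dtype=float) * self.y_std + self.y_mean

    def to_dict(self):
        return {k: getattr(self, k).tolist()
                for k in ("v_mean", "v_std", "y_mean", "y_std")}

    @classmethod
    def from_dict(cls, d):
        return cls(**{k: np.asarray(d[k], dtype=float)
                      for k in ("v_mean", "v_std", "y_mean", "y_std")})


@dataclass
class Dataset:
    """Simulator-generated input-output pairs with split labels.

    ``V`` is (N, 23) in parameter units, ``Y`` is (N, 16) in clinical output
    units.  ``splits`` labels each row train/test/validation.  ``stats`` are
    computed from the training split only.
    """

    V: np.ndarray
    Y: np.ndarray
    splits: np.ndarray | None = None
    stats: NormalizationStats | None = None
    prior_preset: str = "custom"
    seed: int | None = None
    n_failed: int = 0

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.V.shape[0] != self.Y.shape[0]:
            raise CVSimError("V and Y row counts differ")

    def __len__(self) -> int:
        return self.V.shape[0]

    def rows(self, split: str) -> np.ndarray:
        if self.splits is None:
            raise CVSimError("dataset has not been split yet")
        return np.flatnonzero(self.splits == split)

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.rows(split)
        return self.V[idx], self.Y[idx]

    # -- persistence --------------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("V", data=self.V)
            f.create_dataset("Y", data=self.Y)
            if self.splits is not None:
                f.create_dataset(
                    "splits", data=np.char.encode(self.splits.astype(str)))
            meta = {"prior_preset": self.prior_preset, "seed": self.seed,
                    "n_failed": self.n_failed}
            if self.stats is not None:
                meta["stats"] = self.stats.to_dict()
            f.attrs["meta"] = json.dumps(meta)

    @classmethod
    def from_hdf5(cls, path) -> "Dataset":
        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            splits = None
            if "splits" in f:
                splits = np.char.decode(f["splits"][:]).astype(object)
            stats = (NormalizationStats.from_dict(meta["stats"])
                     if "stats" in meta else None)
            return cls(V=f["V"][:], Y=f["Y"][:], splits=splits, stats=stats,
                       prior_preset=meta.get("prior_preset", "custom"),
                       seed=meta.get("seed"),
                       n_failed=meta.get("n_failed", 0))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            np.hstack([self.V, self.Y]),
            columns=[*PARAM_NAMES, *OUTPUT_NAMES])
        if self.splits is not None:
            df["split"] = self.splits
        df.to_csv(path, index=False)


def build_dataset(V, sim_config: SimulationConfig | None = None,
                  prior_preset: str = "custom",
                  seed: int | None = None,
                  progress: bool = False) -> Dataset:
    """Run the simulator on every parameter row of ``V`` (n, 23).

    Rows whose simulation fails (invalid parameters or non-convergent
    integration) are dropped and logged; more than 50% failures aborts.
    """
    cfg = sim_config or GENERATION_CONFIG
    V = np.atleast_2d(np.asarray(V, dtype=float))
    iterator = range(V.shape[0])
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="simulating", unit="run")
        except ImportError:  # pragma: no cover
            pass
    keep, ys = [], []
    n_failed = 0
    for i in iterator:
        try:
            params = ParameterSet.from_array(V[i])
            traj = simulate(params, cfg)
        except CVSimError as exc:
            n_failed += 1
            logger.warning("dropping row %d: %s", i, exc)
            continue
        if not traj.ok:
            n_failed += 1
            logger.warning("dropping row %d: %s", i, traj.message)
            continue
        keep.append(i)
        ys.append(extract_outputs(traj, params).to_array())
    if n_failed > 0.5 * V.shape[0]:
        raise CVSimError(
            f"{n_failed}/{V.shape[0]} simulations failed; check the prior "
            f"and solver settings")
    ds = Dataset(V=V[keep], Y=np.asarray(ys), prior_preset=prior_preset,
                 seed=seed, n_failed=n_failed)
    logger.info("built dataset: %d kept, %d dropped", len(ds), n_failed)
    return ds


def split_dataset(dataset: Dataset, scheme: str = "synthetic",
                  seed: int | np.random.Generator = 0) -> Dataset:
    """Label rows train / online-test / offline-validation.

    Both schemes reserve a validation fraction of 4000/54000 and divide the
    remainder 3:1 into training and online testing, reproducing the
    full-scale counts 37500/12500/4000 at N = 54000 and keeping the same
    ratios at reduced scale.  Splits are disjoint, exhaustive and
    seed-reproducible.
    """
    if scheme not in ("synthetic", "ehr"):
        raise CVSimError(f"unknown split scheme {scheme!r}")
    n = len(dataset)
    n_valid = int(round(n * FULL_SCALE_VALID / FULL_SCALE_N))
    n_train = int(round((n - n_valid) * 0.75))
    n_test = n - n_valid - n_train
    if min(n_valid, n_train, n_test) < 1:
        raise CVSimError(f"dataset of size {n} too small to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[perm[:n_train]] = SPLIT_TRAIN
    labels[perm[n_train:n_train + n_test]] = SPLIT_TEST
    labels[perm[n_train + n_test:]] = SPLIT_VALID
    dataset.splits = labels
    dataset.stats = compute_normalization(dataset)
    return dataset


def compute_normalization(dataset: Dataset) -> NormalizationStats:
    """Per-feature z-score statistics from the training split only."""
    V, Y = dataset.subset(SPLIT_TRAIN)
    return NormalizationStats(
        v_mean=V.mean(axis=0), v_std=_safe_std(V),
        y_mean=Y.mean(axis=0), y_std=_safe_std(Y))


def _safe_std(X: np.ndarray) -> np.ndarray:
    s = X.std(axis=0)
    return np.where(s > 0, s, 1.0)


# ---------------------------------------------------------------------------
# Synthetic EHR-style tables
# ---------------------------------------------------------------------------

#: Default per-attribute observation probabilities, shaped after the
#: clinical cohort the pipeline targets: routine attributes (heart rate,
#: arterial pressures, cardiac output...) nearly always present, invasive or
#: imaging-derived ones (right-heart pressures, ventricular volumes) sparse.
DEFAULT_OBSERVATION_PROBS = {
    "Hr": 1.0, "Pa_sys": 1.0, "Pa_dia": 1.0,
    "Pr_sys": 0.95, "Pr_dia": 0.25, "Ppa_sys": 1.0, "Ppa_dia": 1.0,
    "Pr_edp": 0.95, "Pw": 1.0, "Pcvp": 0.07,
    "Vl_sys": 0.0, "Vl_dia": 0.07, "LVEF": 0.97,
    "CO": 1.0, "SVR": 1.0, "PVR": 1.0,
}


def synthesize_ehr_table(dataset: Dataset,
                         observation_probs: dict[str, float] | None = None,
                         noise: NoiseModel | None = None,
                         n_patients: int = 84,
                         seed: int | np.random.Generator = 0):
    """Build an EHR-style table from simulated outputs: noisy observed cells,
    empty (NaN) missing cells, ground truth retained for recovery tests.

    Rows are drawn (without replacement when possible) from the dataset;
    each attribute is observed independently with its specified probability.

    Returns ``(table, truth)``: a DataFrame with ``patient`` + 16 attribute
    columns (NaN = missing), and a DataFrame of the generating parameter
    rows and noiseless outputs.
    """
    probs = dict(DEFAULT_OBSERVATION_PROBS)
    if observation_probs:
        probs.update(observation_probs)
    bad = {k: v for k, v in probs.items() if not 0.0 <= v <= 1.0}
    if bad:
        raise CVSimError(f"observation probabilities outside [0, 1]: {bad}")
    noise = noise or NoiseModel(delta=0.5)
    rng = np.random.default_rng(seed)
    n = len(dataset)
    idx = (rng.choice(n, size=n_patients, replace=False) if n >= n_patients
           else rng.integers(0, n, size=n_patients))
    Y = dataset.Y[idx]
    Yn = inject_noise(Y, noise, rng)
    p_vec = np.array([probs[name] for name in OUTPUT_NAMES])
    observed = rng.random((n_patients, 16)) < p_vec
    table = pd.DataFrame(np.where(observed, Yn, np.nan),
                         columns=OUTPUT_NAMES)
    table.insert(0, "patient", np.arange(n_patients))
    # parameter columns are prefixed: "Hr" exists in both name spaces
    truth = pd.DataFrame(
        np.hstack([dataset.V[idx], Y]),
        columns=[*("param_" + n for n in PARAM_NAMES), *OUTPUT_NAMES])
    truth.insert(0, "patient", np.arange(n_patients))
    return table, truth


def read_ehr_table(path) -> pd.DataFrame:
    """Read an EHR-style CSV (named attribute columns, empty cell = missing).

    Accepts any subset/ordering of the 16 attribute columns; unknown columns
    other than ``patient`` are rejected.
    """
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in OUTPUT_NAMES
               and c != "patient"]
    if unknown:
        raise CVSimError(f"unknown EHR columns: {unknown}")
    return df
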