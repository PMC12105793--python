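"""Amortized inversion, non-identifiable manifold analysis and
density-ranked imputation of missing clinical measurements.

Because the model has more parameters (23) than clinical targets (16), a
whole manifold ``M_y = {v : f(v) = y}`` maps to one observation.  With a
trained inVAErt bundle, sampling that manifold costs one decoder evaluation
per standard-normal latent draw.  Solutions are verified by pushing the
decoded parameters back through the exact simulator (synthetic studies) or
the fast emulator (clinical-cohort pipeline), and the manifold's intrinsic
dimension is probed with an SVD / cumulative-energy analysis.

Missing components of an observation are completed by physics-based
multiple imputation: draw candidates from the flow, keep those matching the
observed components, overwrite the observed entries with the measurements,
and rank the completions by flow log-density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cvsim6 import (
    OUTPUT_NAMES,
    OUTPUT_STDS,
    PARAM_NAMES,
    ClinicalOutputs,
    CVSimError,
    ParameterSet,
    SimulationConfig,
    extract_outputs,
    simulate,
)
from .data import GENERATION_CONFIG, PriorSpec
from .networks import TrainedInVAErt, decode, flow_log_density, flow_sample


@dataclass
class ManifoldSamples:
    """Decoded solutions of one inverse problem.

    ``W`` holds the latent draws (Nw, dim_w), ``V_hat`` the decoded
    parameters (Nw, 23) and, once verified, ``Y_hat`` the re-evaluated
    outputs (Nw, 16) through the declared evaluator.
    """

    y: np.ndarray                       # (16,) the inverted observation
    W: np.ndarray
    V_hat: np.ndarray
    Y_hat: np.ndarray | None = None
    evaluator: str | None = None        # "exact" | "emulator"
    mask: np.ndarray | None = None      # observed flags of the original y
    failed_rows: list = field(default_factory=list)


@dataclass
class ErrorReport:
    """Componentwise reconstruction-error summary |y - y_hat|.

    ``average``, ``max`` and ``sd`` are per-component statistics of the
    absolute error across solutions (physical units);
    ``max_relative_error`` aggregates |y-y_hat|/|y| over components and
    solutions.
    """

    components: list[str]
    average: np.ndarray
    max: np.ndarray
    sd: np.ndarray
    max_relative_error: float
    n_solutions: int
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"average": self.average, "max": self.max, "sd": self.sd},
            index=self.components)


def _as_output_array(y) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(y, ClinicalOutputs):
        return y.to_array(), y.mask
    return np.asarray(y, dtype=float), None


def invert(model: TrainedInVAErt, y, Nw: int = 100,
           seed: int | np.random.Generator = 0,
           clip_to_prior: PriorSpec | None = None) -> ManifoldSamples:
    """Draw ``Nw`` latent samples and decode each against the fixed,
    complete observation ``y`` (physical units).

    Observations with missing entries must first be completed (see
    :func:`impute_and_rank`).  ``clip_to_prior`` optionally projects
    decoded parameters onto the prior box (decoder outputs are
    unconstrained and can leave the physical domain for out-of-range
    observations); by default predictions are returned as-is.
    """
    y_arr, mask = _as_output_array(y)
    if mask is not None and not np.all(mask):
        raise CVSimError("observation has missing entries; run it through "
                         "impute_and_rank first")
    if not np.all(np.isfinite(y_arr)):
        raise CVSimError("observation has non-finite entries; run it "
                         "through impute_and_rank first")
    if Nw < 1:
        raise CVSimError(f"Nw must be >= 1, got {Nw}")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((Nw, model.config.dim_w))
    V_hat = decode(model.decoder, np.tile(y_arr, (Nw, 1)), W, model.stats)
    if clip_to_prior is not None:
        V_hat = np.clip(V_hat, clip_to_prior.lower, clip_to_prior.upper)
    return ManifoldSamples(y=y_arr, W=W, V_hat=V_hat)


def verify_solutions(samples: ManifoldSamples,
                     model: TrainedInVAErt | None = None,
                     evaluator: str = "exact",
                     sim_config: SimulationConfig | None = None
                     ) -> ErrorReport:
    """Re-evaluate decoded parameters and summarize |y - y_hat|.

    ``evaluator`` is ``"exact"`` (the numerical simulator; failures are
    recorded per-row and excluded from the statistics) or ``"emulator"``
    (requires ``model``).  Fills ``samples.Y_hat`` in place.
    """
    if evaluator not in ("exact", "emulator"):
        raise CVSimError(f"unknown evaluator {evaluator!r}")
    n = samples.V_hat.shape[0]
    failed: list[int] = []
    if evaluator == "emulator":
        if model is None:
            raise CVSimError("emulator evaluation needs the trained model")
        Y_hat = model.stats.denormalize_y(model.emulator.forward_array(
            model.stats.normalize_v(samples.V_hat)))
    else:
        cfg = sim_config or GENERATION_CONFIG
        Y_hat = np.full((n, 16), np.nan)
        for i in range(n):
            try:
                params = ParameterSet.from_array(samples.V_hat[i])
                traj = simulate(params, cfg)
            except CVSimError:
                failed.append(i)
                continue
            if not traj.ok:
                failed.append(i)
                continue
            Y_hat[i] = extract_outputs(traj, params).to_array()
    samples.Y_hat = Y_hat
    samples.evaluator = evaluator
    samples.failed_rows = failed
    ok = np.setdiff1d(np.arange(n), failed)
    if ok.size == 0:
        raise CVSimError("all re-evaluations failed")
    err = np.abs(Y_hat[ok] - samples.y)
    rel = err / np.abs(samples.y)
    return ErrorReport(
        components=list(OUTPUT_NAMES),
        average=err.mean(axis=0), max=err.max(axis=0), sd=err.std(axis=0),
        max_relative_error=float(rel.max()),
        n_solutions=int(ok.size), n_failed=len(failed))


def manifold_spectrum(V_hat) -> tuple[np.ndarray, np.ndarray]:
    """Singular values of the column-centered sample matrix and the
    cumulative energy CE_n = sum_{i<=n} s_i^2 / sum_i s_i^2.

    A rank-degenerate sample (all rows identical) returns CE = [1, ...]
    with a warning.
    """
    V_hat = np.asarray(V_hat, dtype=float)
    if V_hat.shape[0] < 2:
        raise CVSimError("need at least 2 samples for an SVD spectrum")
    X = V_hat - V_hat.mean(axis=0)
    s = np.linalg.svd(X, compute_uv=False)
    total = np.sum(s ** 2)
    if total == 0.0:
        warnings.warn("degenerate manifold sample: zero variance",
                      UserWarning)
        ce = np.ones_like(s)
        ce[:] = 1.0
        return s, ce
    return s, np.cumsum(s ** 2) / total


@dataclass
class ImputationResult:
    """Ranked complete-output candidates for a partially observed y.

    Candidates are sorted by non-increasing flow log-density; in every
    candidate the observed components equal the measurements exactly.
    """

    candidates: np.ndarray          # (K, 16) physical units
    log_densities: np.ndarray       # (K,)
    mask: np.ndarray                # True = observed
    n_pool: int
    n_matched: int
    widened: bool = False


def impute_and_rank(model: TrainedInVAErt, y_partial, mask=None,
                    M: int = 5000, K: int = 4, match_tol: float = 3.0,
                    seed: int | np.random.Generator = 0) -> ImputationResult:
    """Physics-based multiple imputation of missing output components.

    Draw ``M`` flow samples; retain candidates whose observed components
    all lie within ``match_tol`` measurement standard deviations of the
    measurements; overwrite the observed entries with the measurements;
    rank by flow log-density and return the top ``K``.  If nothing matches,
    the tolerance is effectively widened to the nearest candidates (with a
    warning).

    ``y_partial`` may be a :class:`ClinicalOutputs` with a mask, an array
    with NaNs at missing entries, or an array plus explicit ``mask``.
    """
    y_arr, obj_mask = _as_output_array(y_partial)
    if mask is None:
        mask = obj_mask if obj_mask is not None else np.isfinite(y_arr)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise CVSimError("at least one component must be observed")
    if K < 1 or M < K:
        raise CVSimError("need M >= K >= 1 candidate draws")
    rng = np.random.default_rng(seed)
    if mask.all():
        lp = flow_log_density(model.flow, y_arr[None, :], model.stats)
        return ImputationResult(candidates=y_arr[None, :].copy(),
                                log_densities=lp, mask=mask,
                                n_pool=0, n_matched=1)
    pool = flow_sample(model.flow, M, rng, model.stats)
    dev = np.abs(pool[:, mask] - y_arr[mask]) / OUTPUT_STDS[mask]
    worst = dev.max(axis=1)
    matched = np.flatnonzero(worst <= match_tol)
    widened = False
    if matched.size == 0:
        warnings.warn(
            f"no flow candidate matched the observed components within "
            f"{match_tol} standard deviations; falling back to the nearest "
            f"candidates", UserWarning)
        matched = np.argsort(worst)[:K]
        widened = True
    candidates = pool[matched]
    candidates[:, mask] = y_arr[mask]
    lp = flow_log_density(model.flow, candidates, model.stats)
    order = np.argsort(-lp)[:K]
    return ImputationResult(candidates=candidates[order],
                            log_densities=lp[order], mask=mask,
                            n_pool=M, n_matched=int(matched.size),
                            widened=widened)


# ---------------------------------------------------------------------------
# Clinical-cohort (EHR) pipeline
# ---------------------------------------------------------------------------

MIN_OBSERVED = 11  # inversion requires more than 10 of the 16 attributes


def ehr_pipeline(model: TrainedInVAErt, table: pd.DataFrame,
                 Nw: int = 100, seed: int = 0,
                 M: int = 5000, match_tol: float = 3.0,
                 min_observed: int = MIN_OBSERVED
                 ) -> tuple[dict[int, ManifoldSamples], list[int]]:
    """Amortized inversion of every qualifying patient row of an EHR-style
    table (NaN = missing).

    Per patient: complete the measurement with the top-ranked imputation
    candidate, decode ``Nw`` latent draws, re-evaluate through the fast
    emulator.  Patients with fewer than ``min_observed`` observed
    attributes are skipped and listed.  Returns ``(results, skipped)``
    keyed by the ``patient`` column (or row position).
    """
    cols = [c for c in OUTPUT_NAMES if c in table.columns]
    if not cols:
        raise CVSimError("table has no known attribute columns")
    Y = np.full((len(table), 16), np.nan)
    for j, name in enumerate(OUTPUT_NAMES):
        if name in table.columns:
            Y[:, j] = table[name].to_numpy(dtype=float)
    ids = (table["patient"].to_numpy() if "patient" in table.columns
           else np.arange(len(table)))
    ss = np.random.SeedSequence(seed)
    results: dict[int, ManifoldSamples] = {}
    skipped: list[int] = []
    for row, (pid, y_row) in enumerate(zip(ids, Y)):
        mask = np.isfinite(y_row)
        if mask.sum() == 0:
            raise CVSimError(f"patient {pid}: no observed attributes")
        if mask.sum() < min_observed:
            skipped.append(int(pid))
            continue
        child = np.random.default_rng(ss.spawn(1)[0])
        imp = impute_and_rank(model, y_row, mask=mask, M=M, K=1,
                              match_tol=match_tol, seed=child)
        samples = invert(model, imp.candidates[0], Nw=Nw, seed=child)
        samples.mask = mask
        verify_solutions(samples, model=model, evaluator="emulator")
        results[int(pid)] = samples
    return results, skipped


def componentwise_error(results: dict[int, ManifoldSamples],
                        table: pd.DataFrame) -> pd.DataFrame:
    """Per-attribute inversion error over the cohort:

        e_k = (1/|P_k|) (1/Nw) sum_{q in P_k} sum_i |y_k^(q) - Y_hat_ik^(q)|

    where ``P_k`` is the set of patients with attribute ``k`` observed.
    Attributes observed by no patient are reported as NaN (undefined), with
    their count 0.
    """
    ids = (table["patient"].to_numpy() if "patient" in table.columns
           else np.arange(len(table)))
    rows = []
    for k, name in enumerate(OUTPUT_NAMES):
        total, n_patients = 0.0, 0
        for pid, samples in results.items():
            row = np.flatnonzero(ids == pid)
            if row.size != 1:
                raise CVSimError(f"patient {pid} not found in the table")
            val = (table[name].iloc[row[0]] if name in table.columns
                   else np.nan)
            if not np.isfinite(val):
                continue
            if samples.Y_hat is None:
                raise CVSimError("samples must be verified before scoring")
            total += np.mean(np.abs(val - samples.Y_hat[:, k]))
            n_patients += 1
        rows.append({
            "attribute": name,
            "e_k": total / n_patients if n_patients else np.nan,
            "count": n_patients,
        })
    return pd.DataFrame(rows)


def export_parallel_coordinates(samples: ManifoldSamples,
                                prior: PriorSpec) -> pd.DataFrame:
    """Long-format table of decoded parameter values for parallel-coordinate
    plots: one row per (sample, parameter) with plotting bounds set 5% of
    the prior width beyond the prior box edges."""
    if samples.V_hat.shape[0] == 0:
        raise CVSimError("no samples to export")
    lo, hi = prior.lower, prior.upper
    margin = 0.05 * (hi - lo)
    rows = []
    for i in range(samples.V_hat.shape[0]):
        for j, name in enumerate(PARAM_NAMES):
            rows.append({
                "parameter": name, "sample": i,
                "value": samples.V_hat[i, j],
                "lower_bound": lo[j] - margin[j],
                "upper_bound": hi[j] + margin[j],
            })
    return pd.DataFrame(rows)
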