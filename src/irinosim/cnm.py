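"""Cluster Newton method (stage 1) for multi-solution parameter estimation.

The PBPK model has 46 unknown kinetic parameters but the fitting data — a
mean concentration-time profile of five compounds — constrain far fewer
combinations, so a single "best" parameter vector is meaningless.  The
Cluster Newton method instead evolves a whole cloud of parameter vectors:

1. sample N vectors log-uniformly inside per-parameter ranges;
2. fit an affine surrogate ``r ~ A x + b`` of the residual map across the
   cloud by least squares (the system is underdetermined: 5 objectives, 46
   parameters);
3. move every member by the minimum-norm Newton step ``A dx = -r`` plus a
   small random perturbation that preserves cloud diversity, clamp to the
   search ranges, and re-evaluate;
4. iterate until the median residual stalls (stage 1 only — no
   member-wise refinement, to avoid overfitting).

The objective is the log plasma AUC of each compound.  A campaign repeats
the procedure for several independent clouds, pools every member, ranks the
pool by the weighted sum of squared relative errors (WSS) against the
observed profile and keeps the top k sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compounds import COMPOUND_NAMES
from .model import IrinotecanPBPK, SimulationError
from .parameters import PBPKParameterSet

__all__ = [
    "ParameterBounds",
    "ClusterNewtonModel",
    "ClusterNewtonResults",
    "sample_initial_cluster",
    "compute_wss",
    "observed_auc_targets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Bound:
    name: str
    lower: float
    upper: float
    theoretical_lower: float

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.lower < self.theoretical_lower:
            raise ValueError(f"{self.name}: lower below theoretical limit")


class ParameterBounds:
    """Ordered collection of per-parameter search ranges."""

    def __init__(self, bounds: list[Bound]):
        self.bounds = list(bounds)
        self.names = [b.name for b in self.bounds]
        self.lower = np.array([b.lower for b in self.bounds])
        self.upper = np.array([b.upper for b in self.bounds])

    def __len__(self) -> int:
        return len(self.bounds)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "lower": self.lower,
                "upper": self.upper,
                "theoretical_lower": [b.theoretical_lower for b in self.bounds],
            }
        )

    def to_dict(self, values: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, values))


def sample_initial_cluster(
    bounds: ParameterBounds, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` members log-uniformly within every parameter's range.

    The ranges span one to two decades, so a log-uniform prior
    spreads members evenly across scales.  Returns the cluster in log
    space, shape ``(n, n_params)``.
    """
    if n < 2 * len(bounds):
        raise ValueError("cluster must have at least 2 members per parameter")
    lo, hi = np.log(bounds.lower), np.log(bounds.upper)
    return rng.uniform(lo, hi, size=(n, len(bounds)))


def compute_wss(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Weighted sum of squares ``sum((y - y')^2 / y^2)`` over all points.

    Points with a non-positive observation carry no information about the
    relative error and are excluded with a warning.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must be aligned")
    ok = observed > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} non-positive observations from WSS",
            RuntimeWarning,
            stacklevel=2,
        )
    resid = (observed[ok] - predicted[ok]) / observed[ok]
    return float(np.sum(resid**2))


def observed_auc_targets(
    observed: pd.DataFrame, extrapolate: bool = True
) -> dict[str, float]:
    """Per-compound AUC of the observed profile (nM*h).

    Trapezoid to the last sampling time plus, when ``extrapolate`` is set,
    the standard non-compartmental log-linear tail ``C_last / lambda_z``
    with the terminal slope fitted to the last three positive points — so
    the stage-1 targets are AUC(0-inf) estimates comparable to the model's
    analytic AUCs.
    """
    targets = {}
    for comp, grp in observed.groupby("compound"):
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy()
        c = grp["concentration_nM"].to_numpy()
        auc = float(np.trapezoid(c, t))
        if extrapolate and len(c) >= 3 and np.all(c[-3:] > 0):
            slope = np.polyfit(t[-3:], np.log(c[-3:]), 1)[0]
            if slope < 0:
                auc += float(c[-1] / -slope)
        targets[comp] = auc
    return targets


class ClusterNewtonModel:
    """CNM fitting problem for the irinotecan PBPK model.

    Parameters
    ----------
    observed
        Tidy frame (time_h, compound, concentration_nM) of observed blood
        concentrations; the per-compound trapezoidal AUCs are the stage-1
        objective and the full profile is used for WSS ranking.
    bounds
        Search ranges of the 46 unknowns (reciprocal quantities enter on
        their conventional scales, e.g. 1/beta).
    template
        Parameter set supplying everything the search does not touch
        (disposition, physiology, regimen).
    builder
        Callable mapping ``(values_dict, template)`` to a
        :class:`PBPKParameterSet` (see
        :func:`irinosim.fixtures.vector_to_params`).
    """

    def __init__(
        self,
        observed: pd.DataFrame,
        bounds: ParameterBounds,
        template: PBPKParameterSet,
        builder,
        auc_targets: dict[str, float] | None = None,
    ):
        self.observed = observed.sort_values(["compound", "time_h"]).reset_index(
            drop=True
        )
        self.bounds = bounds
        self.template = template
        self.builder = builder
        self.auc_targets = auc_targets or observed_auc_targets(observed)
        missing = [c for c in COMPOUND_NAMES if c not in self.auc_targets]
        if missing:
            raise ValueError(f"no AUC target for {missing}")
        self._log_target = np.log(
            [self.auc_targets[c] for c in COMPOUND_NAMES]
        )
        self._obs_times = np.sort(self.observed["time_h"].unique())

    # -- objective -------------------------------------------------------
    def params_from_log(self, x: np.ndarray) -> PBPKParameterSet:
        return self.builder(self.bounds.to_dict(np.exp(x)), self.template)

    def _log_auc(self, x: np.ndarray) -> np.ndarray:
        params = self.params_from_log(x)
        pbpk = IrinotecanPBPK(params)
        auc = pbpk.exposures().auc_plasma
        vals = np.array([auc[c] for c in COMPOUND_NAMES])
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise SimulationError("non-positive AUC")
        return np.log(vals)

    def residuals(self, cluster: np.ndarray) -> np.ndarray:
        """Log-AUC residual matrix (n_members x 5); failures become NaN."""
        out = np.full((cluster.shape[0], len(COMPOUND_NAMES)), np.nan)
        for j, x in enumerate(cluster):
            try:
                out[j] = self._log_auc(x) - self._log_target
            except (SimulationError, np.linalg.LinAlgError, ValueError):
                pass
        return out

    def _log_observed_vector(self) -> np.ndarray:
        obs = self.observed
        ok = obs["concentration_nM"] > 0
        return np.log(obs.loc[ok, "concentration_nM"].to_numpy())

    def profile_residuals(self, cluster: np.ndarray) -> np.ndarray:
        """Log-concentration residuals at every observed point (n x n_obs)."""
        obs = self.observed
        ok = (obs["concentration_nM"] > 0).to_numpy()
        log_obs = np.log(obs.loc[ok, "concentration_nM"].to_numpy())
        out = np.full((cluster.shape[0], ok.sum()), np.nan)
        for j, x in enumerate(cluster):
            try:
                pbpk = IrinotecanPBPK(self.params_from_log(x))
                pred = pbpk.profile_at(self._obs_times)
                merged = obs.merge(
                    pred, on=["time_h", "compound"], suffixes=("", "_pred")
                )
                vals = merged.loc[ok, "concentration_nM_pred"].to_numpy()
                if np.all(vals > 0):
                    out[j] = np.log(vals) - log_obs
            except (SimulationError, np.linalg.LinAlgError, ValueError):
                pass
        return out

    def step(
        self,
        cluster: np.ndarray,
        resid: np.ndarray,
        rng: np.random.Generator,
        perturbation: float = 0.05,
        ridge: float = 1e-8,
    ) -> np.ndarray:
        """One stage-1 update of the whole cluster (returns new cluster)."""
        ok = np.all(np.isfinite(resid), axis=1)
        if ok.sum() < len(self.bounds) // 4:
            raise SimulationError("too few evaluable cluster members")
        X = np.column_stack([cluster[ok], np.ones(ok.sum())])
        # affine surrogate r ~ A x + b by least squares
        coef, *_ = np.linalg.lstsq(X, resid[ok], rcond=None)
        A = coef[:-1].T  # (5, n_params)
        # minimum-norm Newton step: dx = -pinv(A) r
        try:
            pinv = np.linalg.pinv(A, rcond=1e-10)
        except np.linalg.LinAlgError:  # pragma: no cover
            logger.warning("surrogate rank-deficient; ridge-regularized solve")
            pinv = A.T @ np.linalg.inv(A @ A.T + ridge * np.eye(A.shape[0]))
        new = cluster.copy()
        r_fill = np.where(np.isfinite(resid), resid, 0.0)
        new -= r_fill @ pinv.T
        # diversity-preserving random perturbation, fraction of log-range
        span = np.log(self.bounds.upper) - np.log(self.bounds.lower)
        new += rng.uniform(-1, 1, size=new.shape) * perturbation * span
        # failed members are resampled inside the box
        if (~ok).any():
            lo, hi = np.log(self.bounds.lower), np.log(self.bounds.upper)
            new[~ok] = rng.uniform(lo, hi, size=(int((~ok).sum()), len(self.bounds)))
        return np.clip(new, np.log(self.bounds.lower), np.log(self.bounds.upper))

    def run_stage1(
        self,
        n: int,
        rng: np.random.Generator,
        max_iter: int = 10,
        tol_median_rel: float = 0.05,
        perturbation: float = 0.05,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Evolve one cloud; returns (cluster, residuals) after stage 1.

        Drives the per-compound AUC residuals toward zero with a
        geometrically decaying diversity perturbation, stopping early when
        the median relative AUC error falls below ``tol_median_rel``.
        """
        cluster = sample_initial_cluster(self.bounds, n, rng)
        resid = self.residuals(cluster)
        pert = perturbation
        for _ in range(max_iter):
            med = np.nanmedian(np.abs(np.expm1(resid)))
            if med < tol_median_rel:
                break
            cluster = self.step(cluster, resid, rng, pert)
            resid = self.residuals(cluster)
            pert = max(0.2 * perturbation, pert * 0.7)
        return cluster, resid

    def _member_wss_vector(self, cluster: np.ndarray) -> np.ndarray:
        """WSS of every member (sum of squared relative profile errors)."""
        presid = self.profile_residuals(cluster)
        out = np.full(cluster.shape[0], np.inf)
        ok = np.all(np.isfinite(presid), axis=1)
        out[ok] = np.sum((np.exp(presid[ok]) - 1.0) ** 2, axis=1)
        return out

    def refine_member(
        self,
        x: np.ndarray,
        rng: np.random.Generator,
        max_iter: int = 30,
        n_local: int = 55,
        radius: float = 0.05,
        tol: float = 1e-3,
    ) -> tuple[np.ndarray, float]:
        """Local cluster Newton polish of one member on the WSS objective.

        A small cloud is sampled inside a shrinking trust region around the
        member; the affine surrogate fitted to that local cloud provides a
        regression Jacobian of the log-concentration residuals, and damped
        Gauss-Newton steps (with step halving) descend the WSS.  This is
        the same surrogate machinery as the global stage, applied locally —
        a desk-scale substitute for the profile agreement a production-scale
        campaign buys with a million-member pool.
        """
        lo, hi = np.log(self.bounds.lower), np.log(self.bounds.upper)
        x = x.copy()
        fx = self._member_wss_vector(x[None])[0]
        r = radius
        for _ in range(max_iter):
            pts = np.vstack(
                [
                    x[None],
                    np.clip(
                        x + rng.uniform(-r, r, size=(n_local, len(x))) * (hi - lo),
                        lo,
                        hi,
                    ),
                ]
            )
            presid = self.profile_residuals(pts)
            rx = presid[0]
            ok = np.all(np.isfinite(presid), axis=1)
            if not ok[0] or ok.sum() < len(x) // 2:
                r *= 0.6
                continue
            X = np.column_stack([pts[ok], np.ones(ok.sum())])
            coef, *_ = np.linalg.lstsq(X, presid[ok], rcond=None)
            A = coef[:-1].T
            step, *_ = np.linalg.lstsq(A, -rx, rcond=None)
            improved = False
            for alpha in (1.0, 0.5, 0.25, 0.1):
                cand = np.clip(x + alpha * step, lo, hi)
                fc = self._member_wss_vector(cand[None])[0]
                if fc < fx:
                    x, fx = cand, fc
                    improved = True
                    break
            local_wss = np.full(len(pts), np.inf)
            local_wss[ok] = np.sum((np.exp(presid[ok]) - 1.0) ** 2, axis=1)
            if local_wss.min() < fx:
                x = pts[int(np.argmin(local_wss))].copy()
                fx = float(local_wss.min())
                improved = True
            if not improved:
                r *= 0.6
            if fx < tol:
                break
        return x, float(fx)

    def member_wss(self, x: np.ndarray) -> float:
        """WSS of one member's profile against the observed profile."""
        pbpk = IrinotecanPBPK(self.params_from_log(x))
        pred = pbpk.profile_at(self._obs_times)
        merged = self.observed.merge(
            pred, on=["time_h", "compound"], suffixes=("", "_pred")
        )
        return compute_wss(
            merged["concentration_nM"].to_numpy(),
            merged["concentration_nM_pred"].to_numpy(),
        )

    # -- campaign --------------------------------------------------------
    def fit(
        self,
        batches: int = 100,
        cluster_size: int = 10_000,
        top_k: int = 30,
        seed: int = 0,
        max_iter: int = 10,
        perturbation: float = 0.05,
        wss_pool_fraction: float = 0.3,
        refine_elites: int = 5,
        refine_iter: int = 30,
    ) -> "ClusterNewtonResults":
        """Run a CNM campaign and rank the pooled members by WSS.

        ``wss_pool_fraction`` < 1 restricts the (expensive) WSS profile
        simulation to that fraction of the pool with the smallest AUC
        residual norm.  The ``refine_elites`` best-WSS members are then
        polished with :meth:`refine_member` before the final ranking.
        """
        pool, pool_resid, batch_ids = [], [], []
        for b in range(batches):
            rng = np.random.default_rng(seed + b)
            cluster, resid = self.run_stage1(
                cluster_size, rng, max_iter=max_iter, perturbation=perturbation
            )
            pool.append(cluster)
            pool_resid.append(resid)
            batch_ids.append(np.full(cluster.shape[0], b))
        members = np.concatenate(pool)
        resid = np.concatenate(pool_resid)
        batch_ids = np.concatenate(batch_ids)
        ok = np.all(np.isfinite(resid), axis=1)
        if not ok.any():
            raise SimulationError("every campaign member failed simulation")
        norm = np.where(ok, np.linalg.norm(resid, axis=1), np.inf)
        n_rank = max(top_k, int(np.ceil(wss_pool_fraction * ok.sum())))
        candidates = np.argsort(norm, kind="stable")[:n_rank]
        wss = np.full(members.shape[0], np.inf)
        wss[candidates] = self._member_wss_vector(members[candidates])
        # elite polish: local cluster Newton on the profile objective
        rng = np.random.default_rng(seed + batches)
        elite_order = np.argsort(wss, kind="stable")
        for j in elite_order[: max(0, refine_elites)]:
            if not np.isfinite(wss[j]):
                continue
            members[j], wss[j] = self.refine_member(
                members[j], rng, max_iter=refine_iter
            )
        order = np.lexsort((np.arange(len(wss)), batch_ids, wss))[:top_k]
        order = order[np.isfinite(wss[order])]
        rows = []
        for rank, j in enumerate(order, start=1):
            row = {"ID": rank, "WSS": wss[j], "batch": int(batch_ids[j])}
            row.update(self.bounds.to_dict(np.exp(members[j])))
            rows.append(row)
        return ClusterNewtonResults(self, pd.DataFrame(rows))


class ClusterNewtonResults:
    """Ranked parameter sets from a CNM campaign.

    ``table`` has one row per retained set: ID (ascending WSS), WSS, the
    originating batch, and all searched parameters on their conventional scales.
    """

    def __init__(self, model: ClusterNewtonModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def wss(self) -> np.ndarray:
        return self.table["WSS"].to_numpy()

    def parameter_set(self, set_id: int) -> PBPKParameterSet:
        row = self.table.loc[self.table["ID"] == set_id]
        if row.empty:
            raise KeyError(f"no parameter set with ID {set_id}")
        values = row.iloc[0][self.model.bounds.names].astype(float).to_dict()
        return self.model.builder(values, self.model.template)

    def parameter_sets(self) -> list[PBPKParameterSet]:
        return [self.parameter_set(i) for i in self.table["ID"]]

    def auc_errors(self, set_id: int) -> dict[str, float]:
        """Relative AUC error of one retained set per compound.

        Predicted and observed AUCs are both trapezoids over the observed
        sampling grid, so the comparison is free of extrapolation bias.
        """
        pbpk = IrinotecanPBPK(self.parameter_set(set_id))
        pred = pbpk.profile_at(self.model._obs_times)
        pred_auc = observed_auc_targets(pred, extrapolate=False)
        obs_auc = observed_auc_targets(self.model.observed, extrapolate=False)
        return {c: pred_auc[c] / obs_auc[c] - 1.0 for c in COMPOUND_NAMES}

    def summary(self) -> str:
        lines = [
            "Cluster Newton campaign results",
            "===============================",
            f"retained sets : {len(self.table)}",
            f"WSS range     : {self.wss.min():.4g} - {self.wss.max():.4g}",
            "",
            self.table[["ID", "WSS", "batch"]].to_string(index=False),
        ]
        return "\n".join(lines)
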