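"""Bounded covariance-matrix-adaptation evolution strategy (CMA-ES).

A self-contained implementation of the standard (μ/μ_w, λ) CMA-ES with
cumulative step-size adaptation and rank-one + rank-μ covariance updates,
using the published default strategy constants.  Parameters are affinely
scaled to the unit box by their bounds before optimization; candidates
falling outside the box are repaired by projection and the squared repair
distance is charged as a quadratic fitness penalty at ranking time.

Sampling is deterministic given (seed, generation): each :func:`ask` draws
``standard_normal((λ, n))`` from ``numpy.random.default_rng((seed, gen))``,
so asking twice from the same state yields the same candidates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["CMAConfig", "CMAState", "CMAES"]

_EIG_FLOOR = 1e-20      # floor on covariance eigenvalues
_COND_LIMIT = 1e14      # stop when cond(C) exceeds this
_TOLX = 1e-12           # stop when sigma * sqrt(max eigenvalue) is below this


@dataclass
class CMAConfig:
    popsize: int = 8
    sigma0: float = 0.3          # in scaled space
    seed: int = 0
    max_evals: Optional[int] = None
    penalty_coef: float = 100.0  # quadratic out-of-bounds penalty weight

    def __post_init__(self):
        if self.popsize < 4:
            raise ValueError("popsize must be >= 4")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")


@dataclass
class CMAState:
    mean: np.ndarray
    sigma: float
    C: np.ndarray
    p_sigma: np.ndarray
    p_c: np.ndarray
    generation: int = 0
    evals: int = 0


class CMAES:
    """ask/tell/stop optimizer over box-bounded parameter vectors.

    ``bounds=None`` runs unconstrained in the original coordinates (no
    scaling, no repair); otherwise each coordinate is mapped to [0, 1].
    """

    def __init__(
        self,
        x0: Sequence[float],
        config: CMAConfig = CMAConfig(),
        bounds: Optional[Sequence[tuple[float, float]]] = None,
    ):
        x0 = np.asarray(x0, dtype=float)
        self.n = len(x0)
        self.config = config
        if bounds is not None:
            self.lower = np.array([b[0] for b in bounds], dtype=float)
            self.upper = np.array([b[1] for b in bounds], dtype=float)
            if np.any(self.upper <= self.lower):
                raise ValueError("bounds require min < max in every dimension")
            m0 = (x0 - self.lower) / (self.upper - self.lower)
            if np.any((m0 < 0) | (m0 > 1)):
                raise ValueError("x0 outside bounds")
        else:
            self.lower = self.upper = None
            m0 = x0
        self.state = CMAState(
            mean=m0.copy(),
            sigma=config.sigma0,
            C=np.eye(self.n),
            p_sigma=np.zeros(self.n),
            p_c=np.zeros(self.n),
        )
        # standard strategy constants
        lam = config.popsize
        mu = lam // 2
        w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
        self.weights = w / w.sum()
        self.mu = mu
        self.mu_eff = 1.0 / np.sum(self.weights**2)
        n, mu_eff = self.n, self.mu_eff
        self.c_sigma = (mu_eff + 2) / (n + mu_eff + 5)
        self.d_sigma = 1 + 2 * max(0.0, math.sqrt((mu_eff - 1) / (n + 1)) - 1) + self.c_sigma
        self.c_c = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
        self.c_1 = 2 / ((n + 1.3) ** 2 + mu_eff)
        self.c_mu = min(1 - self.c_1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
        self.chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))
        self._last_raw: Optional[np.ndarray] = None
        self._last_scaled: Optional[np.ndarray] = None
        self._last_penalty: Optional[np.ndarray] = None
        self.best_f = math.inf
        self.best_x: Optional[np.ndarray] = None

    # -- coordinate mapping -------------------------------------------------
    def _to_user(self, z: np.ndarray) -> np.ndarray:
        if self.lower is None:
            return z
        return self.lower + z * (self.upper - self.lower)

    def _decompose(self):
        C = (self.state.C + self.state.C.T) / 2.0
        vals, vecs = np.linalg.eigh(C)
        if np.min(vals) < _EIG_FLOOR:
            warnings.warn("covariance eigenvalue floored (degenerate covariance)")
            vals = np.maximum(vals, _EIG_FLOOR)
            self.state.C = (vecs * vals) @ vecs.T
        return vals, vecs

    # -- ask/tell/stop ------------------------------------------------------
    def ask(self) -> np.ndarray:
        """Sample λ candidates; returns them in original parameter units."""
        st = self.state
        lam = self.config.popsize
        vals, vecs = self._decompose()
        rng = np.random.default_rng((self.config.seed, st.generation))
        z = rng.standard_normal((lam, self.n))
        y = z @ (vecs * np.sqrt(vals)).T  # rows: B D z_i
        raw = st.mean + st.sigma * y
        if self.lower is not None:
            repaired = np.clip(raw, 0.0, 1.0)
            penalty = self.config.penalty_coef * np.sum((raw - repaired) ** 2, axis=1)
        else:
            repaired = raw
            penalty = np.zeros(lam)
        self._last_raw = raw
        self._last_scaled = repaired
        self._last_penalty = penalty
        return np.array([self._to_user(r) for r in repaired])

    def tell(self, candidates: np.ndarray, fitnesses: Sequence[float]) -> None:
        """Rank candidates (penalties included) and update the distribution."""
        st = self.state
        lam = self.config.popsize
        fitnesses = np.asarray(fitnesses, dtype=float)
        if len(candidates) != lam or len(fitnesses) != lam:
            raise ValueError("tell requires exactly popsize candidates and fitnesses")
        nan_mask = np.isnan(fitnesses)
        if nan_mask.any():
            warnings.warn("NaN fitness assigned worst rank")
            worst = np.nanmax(fitnesses) if not np.all(nan_mask) else 0.0
            fitnesses = np.where(nan_mask, worst + 1.0 + np.arange(lam), fitnesses)
        ranked_f = fitnesses + self._last_penalty
        order = np.argsort(ranked_f, kind="stable")  # ties broken by index
        ibest = order[0]
        if ranked_f[ibest] < self.best_f:
            self.best_f = float(ranked_f[ibest])
            self.best_x = self._to_user(self._last_scaled[ibest]).copy()

        # recombination in scaled space, on the *sampled* (unrepaired) points
        sel = self._last_raw[order[: self.mu]]
        old_mean = st.mean.copy()
        new_mean = self.weights @ sel
        y_w = (new_mean - old_mean) / st.sigma

        vals, vecs = self._decompose()
        inv_sqrt = (vecs / np.sqrt(vals)) @ vecs.T
        st.p_sigma = (1 - self.c_sigma) * st.p_sigma + math.sqrt(
            self.c_sigma * (2 - self.c_sigma) * self.mu_eff
        ) * (inv_sqrt @ y_w)
        norm_ps = np.linalg.norm(st.p_sigma)
        h_sigma = norm_ps / math.sqrt(
            1 - (1 - self.c_sigma) ** (2 * (st.generation + 1))
        ) / self.chi_n < 1.4 + 2 / (self.n + 1)
        st.p_c = (1 - self.c_c) * st.p_c + (
            math.sqrt(self.c_c * (2 - self.c_c) * self.mu_eff) * y_w if h_sigma else 0.0
        )
        ys = (sel - old_mean) / st.sigma
        rank_mu = (ys.T * self.weights) @ ys
        delta_h = (1 - h_sigma) * self.c_c * (2 - self.c_c)
        st.C = (
            (1 - self.c_1 - self.c_mu) * st.C
            + self.c_1 * (np.outer(st.p_c, st.p_c) + delta_h * st.C)
            + self.c_mu * rank_mu
        )
        st.sigma = st.sigma * math.exp(
            (self.c_sigma / self.d_sigma) * (norm_ps / self.chi_n - 1)
        )
        st.mean = new_mean
        if self.lower is not None:
            st.mean = np.clip(st.mean, 0.0, 1.0)
        st.generation += 1
        st.evals += lam

    def stop(self) -> list[str]:
        """Termination diagnoses; empty list means keep going."""
        reasons = []
        cfg = self.config
        if cfg.max_evals is not None and self.state.evals >= cfg.max_evals:
            reasons.append("max_evals")
        vals = np.linalg.eigvalsh((self.state.C + self.state.C.T) / 2)
        vmax = max(vals.max(), _EIG_FLOOR)
        vmin = max(vals.min(), _EIG_FLOOR)
        if vmax / vmin > _COND_LIMIT:
            reasons.append("condition_number")
        if self.state.sigma * math.sqrt(vmax) < _TOLX:
            reasons.append("tol_x")
        return reasons

    # convenience driver ----------------------------------------------------
    def optimize(self, func, max_evals: int) -> tuple[np.ndarray, float]:
        """Minimize ``func`` until ``max_evals`` or internal stop."""
        while self.state.evals < max_evals and not self.stop():
            xs = self.ask()
            fs = [func(x) for x in xs]
            self.tell(xs, fs)
        return self.best_x, self.best_f
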