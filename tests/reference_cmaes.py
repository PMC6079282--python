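"""Minimal, independent reference implementation of standard CMA-ES.

Used only as an oracle in tests: unconstrained, written directly from the
published strategy equations with explicit per-step matrices.  Shares the
sampling protocol of the package implementation (one
``standard_normal((lambda, n))`` draw from ``default_rng((seed, gen))``
per generation, candidates ``m + sigma * B D z``) so that trajectories
are comparable at a fixed seed.
"""

import math

import numpy as np


class ReferenceCMA:
    def __init__(self, x0, sigma0, popsize, seed):
        self.n = len(x0)
        self.m = np.asarray(x0, dtype=float).copy()
        self.sigma = float(sigma0)
        self.lam = popsize
        self.seed = seed
        self.gen = 0

        n = self.n
        mu = self.lam // 2
        w = np.array([math.log(mu + 0.5) - math.log(i + 1) for i in range(mu)])
        self.w = w / w.sum()
        self.mu = mu
        self.mueff = 1.0 / float(np.sum(self.w**2))
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.ds = 1 + 2 * max(0.0, math.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(
            1 - self.c1, 2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff)
        )
        self.chiN = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))
        self.ps = np.zeros(n)
        self.pc = np.zeros(n)
        self.C = np.eye(n)

    def step(self, func):
        """One generation: sample, evaluate, update.  Returns (xs, fs)."""
        n, lam = self.n, self.lam
        C = 0.5 * (self.C + self.C.T)
        evals_, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(evals_, 1e-20))
        rng = np.random.default_rng((self.seed, self.gen))
        z = rng.standard_normal((lam, n))
        xs = np.empty((lam, n))
        for i in range(lam):
            xs[i] = self.m + self.sigma * (B @ (D * z[i]))
        fs = np.array([func(x) for x in xs])
        order = np.argsort(fs, kind="stable")

        xsel = xs[order[: self.mu]]
        m_old = self.m.copy()
        self.m = np.zeros(n)
        for i in range(self.mu):
            self.m += self.w[i] * xsel[i]
        yw = (self.m - m_old) / self.sigma

        Cinvsqrt = B @ np.diag(1.0 / D) @ B.T
        self.ps = (1 - self.cs) * self.ps + math.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * (Cinvsqrt @ yw)
        hsig = (
            np.linalg.norm(self.ps)
            / math.sqrt(1 - (1 - self.cs) ** (2 * (self.gen + 1)))
            / self.chiN
            < 1.4 + 2 / (n + 1)
        )
        self.pc = (1 - self.cc) * self.pc
        if hsig:
            self.pc = self.pc + math.sqrt(self.cc * (2 - self.cc) * self.mueff) * yw
        rank_mu = np.zeros((n, n))
        for i in range(self.mu):
            y = (xsel[i] - m_old) / self.sigma
            rank_mu += self.w[i] * np.outer(y, y)
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1
            * (np.outer(self.pc, self.pc) + (1 - hsig) * self.cc * (2 - self.cc) * self.C)
            + self.cmu * rank_mu
        )
        self.sigma = self.sigma * math.exp(
            (self.cs / self.ds) * (np.linalg.norm(self.ps) / self.chiN - 1)
        )
        self.gen += 1
        return xs, fs
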