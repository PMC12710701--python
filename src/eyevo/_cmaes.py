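"""Compact covariance matrix adaptation evolution strategy (CMA-ES).

Standard (mu/mu_w, lambda) CMA-ES with rank-one and rank-mu covariance
updates and cumulative step-size adaptation, operating on a box-constrained
search space (candidates are clipped to [lo, hi]). State is fully
serializable for checkpoint/resume.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CMAES"]


class CMAES:
    """Minimizes f over a box via ask/tell.

    Parameters
    ----------
    x0 : initial mean
    sigma0 : initial step size (same units as x)
    popsize : candidates per generation
    bounds : (lo, hi) scalars applied per coordinate
    seed : generator seed for candidate sampling
    """

    def __init__(self, x0, sigma0: float, popsize: int, seed: int = 0,
                 bounds: tuple[float, float] = (0.0, 1.0)):
        self.dim = len(x0)
        self.mean = np.asarray(x0, dtype=float).copy()
        self.sigma = float(sigma0)
        self.popsize = int(popsize)
        self.bounds = (float(bounds[0]), float(bounds[1]))
        self.rng = np.random.default_rng(seed)

        d, lam = self.dim, self.popsize
        self.mu = lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mu_eff = 1.0 / np.sum(self.weights ** 2)

        self.cc = (4 + self.mu_eff / d) / (d + 4 + 2 * self.mu_eff / d)
        self.cs = (self.mu_eff + 2) / (d + self.mu_eff + 5)
        self.c1 = 2.0 / ((d + 1.3) ** 2 + self.mu_eff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mu_eff - 2 + 1 / self.mu_eff)
                       / ((d + 2) ** 2 + self.mu_eff))
        self.damps = 1 + 2 * max(0.0, np.sqrt((self.mu_eff - 1) / (d + 1)) - 1) \
            + self.cs
        self.chi_n = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d ** 2))

        self.pc = np.zeros(d)
        self.ps = np.zeros(d)
        self.C = np.eye(d)
        self.counteval = 0
        self._eigen()
        self._asked: np.ndarray | None = None
        self._z: np.ndarray | None = None

    def _eigen(self) -> None:
        evals, self.B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(evals, 1e-20))

    def ask(self) -> np.ndarray:
        """Sample popsize candidates, clipped to the box."""
        z = self.rng.standard_normal((self.popsize, self.dim))
        y = z @ np.diag(self.D) @ self.B.T
        x = self.mean + self.sigma * y
        self._z = z
        self._asked = x
        return np.clip(x, *self.bounds)

    def tell(self, solutions: np.ndarray, fitnesses) -> None:
        """Rank-update from (candidate, fitness) pairs; lower is better."""
        fitnesses = np.asarray(fitnesses, dtype=float)
        if len(solutions) != self.popsize or len(fitnesses) != self.popsize:
            raise ValueError("tell expects exactly popsize solutions")
        self.counteval += self.popsize
        order = np.argsort(fitnesses)
        sel = np.asarray(solutions)[order[:self.mu]]

        old_mean = self.mean.copy()
        self.mean = self.weights @ sel
        y_w = (self.mean - old_mean) / self.sigma

        c_inv_sqrt = self.B @ np.diag(1.0 / self.D) @ self.B.T
        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mu_eff) * (c_inv_sqrt @ y_w)
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1 - (1 - self.cs) ** (2 * self.counteval / self.popsize))
                / self.chi_n) < (1.4 + 2 / (self.dim + 1))
        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mu_eff) * y_w

        ys = (sel - old_mean) / self.sigma
        rank_mu = sum(w * np.outer(y, y) for w, y in zip(self.weights, ys))
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (1 - hsig) * self.cc * (2 - self.cc) * self.C)
                  + self.cmu * rank_mu)
        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chi_n - 1))
        self._eigen()

    # -- checkpointing -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dim": self.dim, "mean": self.mean.tolist(), "sigma": self.sigma,
            "popsize": self.popsize, "bounds": list(self.bounds),
            "pc": self.pc.tolist(), "ps": self.ps.tolist(),
            "C": self.C.tolist(), "counteval": self.counteval,
            "rng_state": self.rng.bit_generator.state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CMAES":
        es = cls(d["mean"], d["sigma"], d["popsize"], seed=0,
                 bounds=tuple(d["bounds"]))
        es.pc = np.asarray(d["pc"], dtype=float)
        es.ps = np.asarray(d["ps"], dtype=float)
        es.C = np.asarray(d["C"], dtype=float)
        es.counteval = int(d["counteval"])
        es.rng.bit_generator.state = d["rng_state"]
        es._eigen()
        return es
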