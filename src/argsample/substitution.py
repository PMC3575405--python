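"""Nucleotide substitution models F84 and TN93.

Both models are time-reversible with arbitrary stationary base
frequencies pi and elevated transition rates.  TN93 has two transition
parameters (purine transitions alpha_R, pyrimidine transitions
alpha_Y) relative to the transversion rate beta; F84 is the one-
parameter sub-case obtained with

    alpha_R = beta * (1 + kappa / pi_R),   alpha_Y = beta * (1 + kappa / pi_Y),

where pi_R = pi_A + pi_G and pi_Y = pi_C + pi_T and kappa is the
Felsenstein transition-excess parameter (kappa = 0 recovers F81; the
classical transition/transversion *ratio* is a derived quantity, see
:meth:`F84.ts_tv_ratio`).

The generator is normalized so one unit of branch length equals one
expected substitution per site at stationarity.  P(t) is computed by a
cached spectral decomposition of the symmetrized generator, which is
exact for this reversible family (so Chapman-Kolmogorov holds to
machine precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BaseFrequencies", "SubstitutionModel", "F84", "TN93", "stationary_check"]

# base order everywhere: A, C, G, T
BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
_PURINES = (A, G)
_PYRIMIDINES = (C, T)


@dataclass(frozen=True)
class BaseFrequencies:
    """Stationary nucleotide frequencies (A, C, G, T)."""

    pi: tuple[float, float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.pi, dtype=float)
        if arr.shape != (4,):
            raise ValueError("need exactly 4 frequencies (A, C, G, T)")
        if np.any(arr <= 0) or np.any(arr >= 1):
            raise ValueError("frequencies must lie strictly in (0, 1)")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {arr.sum()}, not 1")

    @classmethod
    def uniform(cls) -> "BaseFrequencies":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_alignment(cls, matrix: np.ndarray) -> "BaseFrequencies":
        """Empirical frequencies from an encoded alignment matrix
        (codes 0..3 = ACGT, >=4 = missing), with a small pseudocount so
        absent bases keep positive frequency."""
        counts = np.bincount(matrix[matrix < 4].ravel(), minlength=4).astype(float)
        counts += 0.5
        p = counts / counts.sum()
        return cls(tuple(p))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)


class SubstitutionModel:
    """Common machinery: normalized generator, spectral P(t)."""

    family = "generic"

    def __init__(self, freqs: BaseFrequencies):
        self.freqs = freqs
        self._decomp = None
        self._pcache: dict[float, np.ndarray] = {}

    # subclasses define the un-normalized exchangeability rates
    def _raw_rates(self) -> tuple[float, float, float]:
        """(alpha_R, alpha_Y, beta) before normalization."""
        raise NotImplementedError

    def rate_matrix(self) -> np.ndarray:
        """Normalized generator Q: rows sum to 0 and
        -sum_i pi_i Q_ii = 1 (one expected substitution per unit time)."""
        pi = self.freqs.as_array()
        alpha_r, alpha_y, beta = self._raw_rates()
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                if (i in _PURINES) and (j in _PURINES):
                    rate = alpha_r
                elif (i in _PYRIMIDINES) and (j in _PYRIMIDINES):
                    rate = alpha_y
                else:
                    rate = beta
                q[i, j] = rate * pi[j]
        np.fill_diagonal(q, 0.0)
        q[np.diag_indices(4)] = -q.sum(axis=1)
        mu = -float(np.dot(pi, np.diag(q)))
        return q / mu

    def _decomposition(self):
        if self._decomp is None:
            pi = self.freqs.as_array()
            q = self.rate_matrix()
            d = np.sqrt(pi)
            s = (q * d[:, None]) / d[None, :]  # symmetric for reversible Q
            s = 0.5 * (s + s.T)
            w, v = np.linalg.eigh(s)
            # Q = D^{-1/2} S D^{1/2}  =>  P(t) = D^{-1/2} V e^{Wt} V^T D^{1/2}
            right = v / d[:, None]
            left = (v * d[:, None]).T
            self._decomp = (w, right, left)
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        """4x4 stochastic matrix P(t) of substitution probabilities over
        a branch of length ``t`` expected substitutions per site."""
        p = self._pcache.get(t)
        if p is not None:
            return p
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        w, right, left = self._decomposition()
        p = (right * np.exp(w * t)) @ left
        np.maximum(p, 0.0, out=p)
        p /= p.sum(axis=1, keepdims=True)
        if len(self._pcache) > 100_000:
            self._pcache.clear()
        self._pcache[t] = p
        return p

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Vectorized P(t) for an array of branch lengths -> (len, 4, 4)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("negative branch length")
        w, right, left = self._decomposition()
        p = np.einsum("ij,tj,jk->tik", right, np.exp(np.outer(ts, w)), left)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p

    def parameters(self) -> dict[str, float]:
        raise NotImplementedError

    def with_parameters(self, **kwargs) -> "SubstitutionModel":
        raise NotImplementedError


class TN93(SubstitutionModel):
    """Tamura-Nei 1993: two transition parameters relative to the
    transversion rate (alpha_R purines, alpha_Y pyrimidines, beta = 1)."""

    family = "TN93"

    def __init__(self, alpha_r: float, alpha_y: float, freqs: BaseFrequencies):
        if alpha_r <= 0 or alpha_y <= 0:
            raise ValueError("transition rates must be positive")
        super().__init__(freqs)
        self.alpha_r = float(alpha_r)
        self.alpha_y = float(alpha_y)

    def _raw_rates(self):
        return self.alpha_r, self.alpha_y, 1.0

    def parameters(self):
        return {"alpha_r": self.alpha_r, "alpha_y": self.alpha_y}

    def with_parameters(self, **kwargs) -> "TN93":
        return TN93(
            kwargs.get("alpha_r", self.alpha_r),
            kwargs.get("alpha_y", self.alpha_y),
            self.freqs,
        )


class F84(SubstitutionModel):
    """Felsenstein 1984: single transition-excess parameter kappa."""

    family = "F84"

    def __init__(self, kappa: float, freqs: BaseFrequencies):
        if kappa < 0:
            raise ValueError("kappa must be nonnegative")
        super().__init__(freqs)
        self.kappa = float(kappa)

    def _raw_rates(self):
        pi = self.freqs.as_array()
        pi_r = pi[A] + pi[G]
        pi_y = pi[C] + pi[T]
        return 1.0 + self.kappa / pi_r, 1.0 + self.kappa / pi_y, 1.0

    def ts_tv_ratio(self) -> float:
        """Expected transition/transversion ratio implied by kappa."""
        pi = self.freqs.as_array()
        pi_r, pi_y = pi[A] + pi[G], pi[C] + pi[T]
        ar, ay, b = self._raw_rates()
        ts = 2 * pi[A] * pi[G] * ar + 2 * pi[C] * pi[T] * ay
        tv = 2 * b * pi_r * pi_y
        return ts / tv

    def as_tn93(self) -> TN93:
        ar, ay, _ = self._raw_rates()
        return TN93(ar, ay, self.freqs)

    def parameters(self):
        return {"kappa": self.kappa}

    def with_parameters(self, **kwargs) -> "F84":
        return F84(kwargs.get("kappa", self.kappa), self.freqs)


def stationary_check(model: SubstitutionModel, ts=(0.01, 0.1, 1.0), tol: float = 1e-10) -> bool:
    """True iff pi^T P(t) = pi^T for each t (stationarity of the
    declared frequencies under the model's transition matrices)."""
    pi = model.freqs.as_array()
    for t in ts:
        if np.max(np.abs(pi @ model.transition_matrix(t) - pi)) > tol:
            return False
    return True
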