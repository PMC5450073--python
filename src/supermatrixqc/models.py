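"""Amino-acid substitution models for the likelihood engine.

A model is a time-reversible 20-state CTMC specified by a symmetric
exchangeability matrix ``S`` and equilibrium frequencies ``pi``:

    Q_ij = S_ij * pi_j   (i != j),   Q_ii = -sum_{j != i} Q_ij,

normalised so the expected number of substitutions per unit branch length,
``-sum_i pi_i Q_ii``, equals 1.  Among-site rate variation uses the
discrete-gamma approximation with equal-probability categories represented
by their category means.

Available empirical matrices: Poisson (uniform), JTT, WAG and LG.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from . import _empirical

N_STATES = 20


def _lower_to_symmetric(lower: list[float]) -> np.ndarray:
    s = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            s[i, j] = s[j, i] = lower[k]
            k += 1
    assert k == len(lower)
    return s


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Category mean rates of the discrete-gamma approximation.

    Equal-probability categories of a Gamma(alpha, mean 1) distribution,
    each represented by its conditional mean; renormalised to average
    exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    bounds = gamma_dist.ppf(np.arange(k + 1) / k, alpha, scale=1.0 / alpha)
    # E[X; a < X < b] for X ~ Gamma(alpha, rate alpha) via the regularised
    # lower incomplete gamma of shape alpha+1.
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * np.where(np.isfinite(bounds[:-1]), bounds[:-1], 0.0))
    upper[-1] = 1.0
    rates = k * (upper - lower)
    return rates / rates.mean()


class SubstitutionModel:
    """Reversible amino-acid model with optional discrete-gamma rates."""

    def __init__(
        self,
        name: str,
        exchangeabilities: np.ndarray,
        frequencies: np.ndarray,
        alpha: float | None = None,
        n_rate_categories: int = 4,
    ):
        s = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if s.shape != (N_STATES, N_STATES) or not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be 20x20 symmetric")
        if np.any(s[~np.eye(N_STATES, dtype=bool)] < 0):
            raise ValueError("off-diagonal exchangeabilities must be non-negative")
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive numbers")
        if alpha is not None and alpha <= 0:
            raise ValueError("gamma shape must be positive")
        self.name = name
        self.exchangeabilities = s
        self.frequencies = pi / pi.sum()
        self.alpha = alpha
        self.n_rate_categories = int(n_rate_categories)

        q = s * self.frequencies[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(self.frequencies, np.diag(q)))
        self.Q = q / mu

        # Symmetrised eigendecomposition: B = D^.5 Q D^-.5 is symmetric for
        # reversible Q, so P(t) = D^-.5 U exp(L t) U' D^.5 with (U, L) = eigh(B).
        sqrt_pi = np.sqrt(self.frequencies)
        b = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
        self._eigvals = eigvals
        self._left = eigvecs / sqrt_pi[:, None]      # D^-.5 U
        self._right = (eigvecs * sqrt_pi[:, None]).T  # U' D^.5
        self._is_poisson = bool(
            np.allclose(s[~np.eye(N_STATES, dtype=bool)], s[0, 1]) and np.allclose(pi, pi[0])
        )

    # -- rate categories ---------------------------------------------------
    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the site-rate mixture; ([1], [1]) without gamma."""
        if self.alpha is None:
            return np.array([1.0]), np.array([1.0])
        rates = discrete_gamma_rates(self.alpha, self.n_rate_categories)
        w = np.full(self.n_rate_categories, 1.0 / self.n_rate_categories)
        return rates, w

    # -- transition probabilities ------------------------------------------
    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), entries clamped to [0, 1]."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if self._is_poisson:
            # 20-state analogue of Jukes-Cantor: closed form avoids the
            # eigen reconstruction in hot loops.
            e = np.exp(-20.0 * t / 19.0)
            p = np.full((N_STATES, N_STATES), (1.0 - e) / 20.0)
            np.fill_diagonal(p, 1.0 / 20.0 + (19.0 / 20.0) * e)
            return p
        p = (self._left * np.exp(self._eigvals * t)) @ self._right
        return np.clip(p, 0.0, 1.0)

    def with_frequencies(self, frequencies: np.ndarray) -> "SubstitutionModel":
        """Same exchangeabilities, different equilibrium (used for biased taxa)."""
        return SubstitutionModel(
            f"{self.name}+F", self.exchangeabilities, frequencies,
            alpha=self.alpha, n_rate_categories=self.n_rate_categories,
        )

    def with_alpha(self, alpha: float | None) -> "SubstitutionModel":
        return SubstitutionModel(
            self.name, self.exchangeabilities, self.frequencies,
            alpha=alpha, n_rate_categories=self.n_rate_categories,
        )

    def __repr__(self) -> str:  # pragma: no cover
        g = f"+G{self.n_rate_categories}(a={self.alpha:g})" if self.alpha else ""
        return f"SubstitutionModel({self.name}{g})"


def _poisson() -> SubstitutionModel:
    s = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(s, 0.0)
    return SubstitutionModel("Poisson", s, np.full(N_STATES, 1.0 / N_STATES))


_BUILDERS = {
    "Poisson": _poisson,
    "JTT": lambda: SubstitutionModel(
        "JTT", _lower_to_symmetric(_empirical.JTT_LOWER), np.array(_empirical.JTT_FREQS)),
    "WAG": lambda: SubstitutionModel(
        "WAG", _lower_to_symmetric(_empirical.WAG_LOWER), np.array(_empirical.WAG_FREQS)),
    "LG": lambda: SubstitutionModel(
        "LG", _lower_to_symmetric(_empirical.LG_LOWER), np.array(_empirical.LG_FREQS)),
}

MODEL_NAMES = tuple(_BUILDERS)


def get_model(name: str, alpha: float | None = None,
              n_rate_categories: int = 4) -> SubstitutionModel:
    """Look up a named model, optionally with discrete-gamma rates."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}") from None
    m = builder()
    if alpha is not None or n_rate_categories != 4:
        m = SubstitutionModel(m.name, m.exchangeabilities, m.frequencies,
                              alpha=alpha, n_rate_categories=n_rate_categories)
    return m


def default_candidates(alpha: float | None = None) -> list[SubstitutionModel]:
    """The model-selection candidate set: Poisson, JTT, WAG, LG."""
    return [get_model(n, alpha=alpha) for n in MODEL_NAMES]
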