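"""PCA thermal contact modes: temperature-sensitive modes of the
contact-frequency x temperature matrix, labelled melting or forming.

Observations are temperatures, variables are contacts. Each contact is
centered across temperatures but *not* variance-scaled: frequencies already
share the [0,1] scale, and unit-variance scaling would inflate noise from
near-constant contacts. Contacts with zero variance across the ladder carry
no mode information and are set aside as "temperature-stable".

Sign convention: every mode is oriented so the linear-regression slope of
its temperature scores against temperature is non-negative. Under column
centering, contacts that melt (frequency decreasing with temperature) then
carry negative loadings and contacts that form carry positive loadings,
making the melting/forming split readable directly from loading sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .contacts import ContactFrequencyMatrix, ContactKey

logger = logging.getLogger(__name__)

MELTING, FORMING, MIXED = "melting", "forming", "mixed"


class ThermalModeError(ValueError):
    pass


@dataclass
class ThermalModeResult:
    """Loadings/scores/explained variance of the thermal contact modes."""

    keys: list[ContactKey]                 # contacts retained for PCA
    stable_keys: list[ContactKey]          # zero-variance contacts, set aside
    temperatures: np.ndarray               # (T,)
    loadings: np.ndarray                   # (n_modes, n_contacts), unit rows
    scores: np.ndarray                     # (T, n_modes)
    explained_variance_ratio: np.ndarray   # (n_modes,), non-increasing
    frequencies: np.ndarray | None = None  # (n_contacts, T) retained rows
    labels: list[str] = field(default_factory=list)

    @property
    def n_modes(self) -> int:
        return self.loadings.shape[0]


def compute_thermal_modes(matrix: ContactFrequencyMatrix,
                          n_modes: int = 2, *,
                          top_k: int | float = 20) -> ThermalModeResult:
    """PCA of the contact matrix with melting/forming mode labels."""
    temps = np.asarray(matrix.temperatures, dtype=float)
    if len(temps) < 3:
        raise ThermalModeError("need at least three temperatures")
    if len(matrix.keys) < 2:
        raise ThermalModeError("need at least two contacts")

    X = matrix.values.T                          # (T, contacts)
    variances = X.var(axis=0)
    # threshold well below any genuine frequency variation (>= (1/frames)^2
    # scale) but above float rounding noise on constant rows (~1e-32)
    varying = variances > 1e-20
    if not np.any(varying):
        raise ThermalModeError("no temperature-dependent variance in matrix")
    stable_keys = [k for k, v in zip(matrix.keys, varying) if not v]
    keys = [k for k, v in zip(matrix.keys, varying) if v]
    if stable_keys:
        logger.info("%d temperature-stable contacts set aside", len(stable_keys))
    Xv = X[:, varying]

    max_modes = min(len(temps) - 1, Xv.shape[1])
    if n_modes > max_modes:
        raise ThermalModeError(
            f"n_modes={n_modes} exceeds min(temperatures-1, contacts)={max_modes}")
    pca = PCA(n_components=n_modes, svd_solver="full")
    scores = pca.fit_transform(Xv - Xv.mean(axis=0))
    loadings = pca.components_
    evr = pca.explained_variance_ratio_

    # orient: slope of scores vs temperature non-negative
    for m in range(n_modes):
        slope = np.polyfit(temps, scores[:, m], 1)[0]
        if slope < 0:
            scores[:, m] = -scores[:, m]
            loadings[m] = -loadings[m]

    result = ThermalModeResult(
        keys=keys, stable_keys=stable_keys, temperatures=temps,
        loadings=loadings, scores=scores, explained_variance_ratio=evr,
        frequencies=Xv.T.copy(),
    )
    result.labels = classify_modes(result, top_k=top_k)
    return result


def classify_modes(result: ThermalModeResult, *,
                   top_k: int | float = 20,
                   majority: float = 0.75) -> list[str]:
    """Label each mode melting / forming / mixed.

    For each of a mode's top-|loading| contacts the temperature trend of
    its frequency profile is rank-correlated (Spearman) with temperature;
    the mode is *melting* if the correlation is negative for at least
    ``majority`` of its top contacts, *forming* if positive for at least
    that fraction, otherwise *mixed*. Observed frequency profiles are used
    when available (mode-only reconstructions of higher modes are residual
    curves and need not be monotone even when the underlying contacts
    are); the mode-reconstructed trend score_m(T) * loading is the
    fallback.
    """
    labels = []
    temps = result.temperatures
    for m in range(result.n_modes):
        ranked = top_contacts(result, m, top_k)
        if len(ranked) < 2:
            logger.warning("mode %d: fewer than 2 top contacts; labelled mixed", m)
            labels.append(MIXED)
            continue
        index = {k: i for i, k in enumerate(result.keys)}
        signs = []
        for key, loading in ranked:
            if result.frequencies is not None:
                trend = result.frequencies[index[key]]
            else:
                trend = result.scores[:, m] * loading
            rho = spearmanr(trend, temps).statistic
            signs.append(np.sign(rho) if np.isfinite(rho) else 0.0)
        signs = np.asarray(signs)
        frac_neg = np.mean(signs < 0)
        frac_pos = np.mean(signs > 0)
        if frac_neg >= majority:
            labels.append(MELTING)
        elif frac_pos >= majority:
            labels.append(FORMING)
        else:
            labels.append(MIXED)
    return labels


def top_contacts(result: ThermalModeResult, mode: int,
                 k: int | float = 20) -> list[tuple[ContactKey, float]]:
    """Contacts of one mode ranked by |loading| (descending).

    ``k`` may be a count or a fraction of the contact set; ties break by
    canonical contact order. If ``k`` exceeds the contact count, all
    contacts are returned with a logged note.
    """
    if not (0 <= mode < result.n_modes):
        raise ThermalModeError(f"mode {mode} does not exist "
                               f"({result.n_modes} modes available)")
    n = len(result.keys)
    if isinstance(k, float) and 0 < k < 1:
        count = int(np.ceil(k * n))
    else:
        count = int(k)
    if count > n:
        logger.info("requested top %d of %d contacts; returning all", count, n)
        count = n
    load = result.loadings[mode]
    order = sorted(range(n), key=lambda i: (-abs(load[i]), result.keys[i].sort_key))
    return [(result.keys[i], float(load[i])) for i in order[:count]]
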