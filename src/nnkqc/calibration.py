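"""Phosphoramidite-ratio calibration.

Model: the probability of incorporating base b at a degenerate position is
proportional to stock_ratio[b] * efficiency[b] — a single-step
multiplicative model with no neighbour or context effects.  Under it the
forward prediction, the efficiency fit and the compensating-stock solve are
exact algebraic inverses (identifiable up to an overall scale, fixed by the
convention G = 1.0):

    predict:  p_b = s_b e_b / sum(s e)
    fit:      e_b proportional to p_b / s_b
    solve:    s_b proportional to t_b / e_b   (t = target composition)

With an equimolar target, an efficiency skew of (G 1.0, A 2/3, T 2/3,
C 0.625) is compensated by stocks G:1.0, A:1.5, T:1.5, C:1.6 for N and
G:1.0, T:1.5 for K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import BASES, K_BASES
from .diagnostics import BiasReport


def _validate(name: str, d: dict[str, float], bases: str) -> None:
    missing = set(bases) - set(d)
    if missing:
        raise ValueError(f"{name} missing bases {sorted(missing)}")
    if any(d[b] <= 0 for b in bases):
        raise ValueError(f"{name} entries must be > 0")


def predict_composition(
    stock: dict[str, float], eff: dict[str, float], bases: str = BASES
) -> dict[str, float]:
    """Effective per-base incorporation probabilities for a base set."""
    _validate("stock", stock, bases)
    _validate("eff", eff, bases)
    w = {b: stock[b] * eff[b] for b in bases}
    total = sum(w.values())
    return {b: w[b] / total for b in bases}


def fit_efficiencies(
    observed: dict[str, float], stock: dict[str, float], bases: str = BASES
) -> dict[str, float]:
    """Invert the incorporation model: efficiencies from an observed
    composition and the stock that produced it, normalised so eff_G = 1."""
    _validate("stock", stock, bases)
    for b in bases:
        if observed.get(b, 0.0) <= 0.0:
            raise ValueError(
                f"observed fraction for {b} is 0; efficiency 0 is outside the model"
            )
    eff = {b: observed[b] / stock[b] for b in bases}
    return {b: eff[b] / eff["G"] for b in bases}


def solve_stock_ratios(
    eff: dict[str, float],
    target: dict[str, float] | None = None,
    bases: str = BASES,
) -> dict[str, float]:
    """Compensating stock ratios such that predict(stock, eff) = target.

    Default target is equimolar.  Normalised to G = 1.0, the convention the
    ratios are quoted in.
    """
    _validate("eff", eff, bases)
    if target is None:
        target = {b: 1.0 / len(bases) for b in bases}
    _validate("target", target, bases)
    stock = {b: target[b] / eff[b] for b in bases}
    return {b: stock[b] / stock["G"] for b in bases}


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted efficiencies, compensating stocks and the residual check."""

    efficiencies: dict[str, float]
    efficiencies_k: dict[str, float]
    solved_stock_n: dict[str, float]
    solved_stock_k: dict[str, float]
    predicted_composition_n: dict[str, float]
    predicted_composition_k: dict[str, float]
    residual: float

    def to_dict(self) -> dict:
        return {
            "efficiencies": dict(self.efficiencies),
            "efficiencies_k": dict(self.efficiencies_k),
            "solved_stock_n": dict(self.solved_stock_n),
            "solved_stock_k": dict(self.solved_stock_k),
            "predicted_composition_n": dict(self.predicted_composition_n),
            "predicted_composition_k": dict(self.predicted_composition_k),
            "residual": self.residual,
        }


def calibrate_from_library(
    report: BiasReport, assumed_stock_n: dict[str, float] | None = None,
    assumed_stock_k: dict[str, float] | None = None,
) -> CalibrationResult:
    """Diagnose a sequenced library and prescribe compensating stock ratios.

    Pools the N-slot (1, 2) compositions across positions by a
    read-weighted mean, fits efficiencies assuming the synthesis used the
    given stock (equimolar by default), and solves for the stock that would
    make the composition equimolar.  K is handled analogously from the
    slot-3 G/T fractions.  Position pooling assumes one efficiency vector
    shared across positions.
    """
    if assumed_stock_n is None:
        assumed_stock_n = {b: 1.0 for b in BASES}
    if assumed_stock_k is None:
        assumed_stock_k = {b: 1.0 for b in K_BASES}
    frac = report.composition.fractions
    pos = report.composition.positions
    weights = pos["n_observations"].to_numpy(dtype=float)
    n_mask = (pos["slot"] != 3).to_numpy()
    k_mask = ~n_mask

    def _pool(mask: np.ndarray, bases: str) -> dict[str, float]:
        w = weights[mask]
        pooled = {
            b: float((frac.loc[mask, b].to_numpy() * w).sum() / w.sum()) for b in bases
        }
        total = sum(pooled.values())
        return {b: v / total for b, v in pooled.items()}

    obs_n = _pool(n_mask, BASES)
    obs_k = _pool(k_mask, K_BASES)
    for b, v in {**obs_n, **obs_k}.items():
        if v <= 0.0:
            raise ValueError(
                f"base {b} absent from the pooled composition; cannot calibrate"
            )
    eff_n = fit_efficiencies(obs_n, assumed_stock_n, BASES)
    eff_k = fit_efficiencies(obs_k, assumed_stock_k, K_BASES)
    stock_n = solve_stock_ratios(eff_n, bases=BASES)
    stock_k = solve_stock_ratios(eff_k, bases=K_BASES)
    pred_n = predict_composition(stock_n, eff_n, BASES)
    pred_k = predict_composition(stock_k, eff_k, K_BASES)
    residual = max(
        max(abs(pred_n[b] - 0.25) for b in BASES),
        max(abs(pred_k[b] - 0.5) for b in K_BASES),
    )
    return CalibrationResult(
        efficiencies=eff_n,
        efficiencies_k=eff_k,
        solved_stock_n=stock_n,
        solved_stock_k=stock_k,
        predicted_composition_n=pred_n,
        predicted_composition_k=pred_k,
        residual=residual,
    )
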