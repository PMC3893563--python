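"""Citrate-phosphate universal buffer design via polyprotic equilibrium.

A McIlvaine-style universal buffer mixes two stocks — disodium hydrogen
phosphate (0.2 M) and citric acid monohydrate (0.1 M) — in varying volume
ratios to reach any pH from roughly 2.5 to 8.  This module solves the full
charge-balance equation of the mixture:

    [H+] + [Na+] = [OH-] + sum over acids of c_total * sum_j j * alpha_j(H+)

where alpha_j is the fraction of the acid carrying j removed protons, given
by its pKa ladder.  The root in pH is found by bisection; an optional Davies
activity correction (iterated on ionic strength) tightens agreement with
bench recipes at the ~0.05-0.6 M ionic strengths these stocks produce.
The solver works on the constant-ionic-medium convention — concentrations
throughout, pH = -log10 [H+], activity entering via Davies-conditional
equilibrium constants — the convention under which the model reproduces
published citrate-phosphate recipe tables most closely.

Dissociation constants are standard 25 degC reference values (they are
package constants, not measurements): citric acid pKa 3.13 / 4.76 / 6.40,
phosphoric acid pKa 2.15 / 7.20 / 12.35, Kw = 1e-14.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AcidSpecies",
    "BufferMixture",
    "BufferRecipe",
    "CITRIC_ACID_PKAS",
    "PHOSPHORIC_ACID_PKAS",
    "PHOSPHATE_STOCK_M",
    "CITRATE_STOCK_M",
    "MM_NA2HPO4",
    "MM_CITRIC_MONOHYDRATE",
    "CITRATE_PHOSPHATE_SERIES",
    "solve_ph",
    "design_recipe",
    "design_series",
    "achievable_span",
    "stock_mass",
    "dilution",
]

# 25 degC standard-table constants
CITRIC_ACID_PKAS = (3.13, 4.76, 6.40)
PHOSPHORIC_ACID_PKAS = (2.15, 7.20, 12.35)
PKW = 14.0
DAVIES_A = 0.509  # Debye-Huckel slope at 25 degC, water

PHOSPHATE_STOCK_M = 0.2
CITRATE_STOCK_M = 0.1
MM_NA2HPO4 = 141.96  # g/mol, anhydrous
MM_CITRIC_MONOHYDRATE = 210.14  # g/mol

#: Bench recipe series: target pH -> (phosphate ml, citrate ml) per 20 ml.
CITRATE_PHOSPHATE_SERIES = {
    2.5: (2.16, 17.84),
    3.0: (4.08, 15.92),
    3.5: (6.04, 13.96),
    4.0: (7.72, 12.28),
    4.5: (9.00, 11.00),
    5.0: (10.28, 9.72),
    5.5: (11.36, 8.64),
    6.0: (12.84, 7.16),
    6.5: (14.20, 5.80),
    7.0: (17.44, 2.56),
    7.5: (17.98, 2.02),
    8.0: (19.53, 0.47),
}


@dataclass(frozen=True)
class AcidSpecies:
    """A polyprotic acid present at a total concentration.

    ``counterion_charge`` is the positive charge delivered per formula unit
    by the salt's cations (2 for Na2HPO4, 0 for free citric acid).
    """

    name: str
    concentration: float  # mol/L in the final mixture
    pkas: tuple[float, ...]
    charge_fully_protonated: int = 0
    counterion_charge: int = 0

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if list(self.pkas) != sorted(self.pkas) or len(set(self.pkas)) != len(self.pkas):
            raise ValueError("pKa list must be strictly ascending")

    def speciation(self, h: float, pka_shift: Sequence[float] | None = None) -> np.ndarray:
        """Fractions alpha_j of the form with j protons removed, j = 0..n."""
        n = len(self.pkas)
        shifts = pka_shift if pka_shift is not None else [0.0] * n
        log_terms = [0.0]
        acc = 0.0
        for i in range(n):
            ka = 10.0 ** -(self.pkas[i] + shifts[i])
            acc += math.log10(ka) - math.log10(h)
            log_terms.append(acc)
        terms = np.power(10.0, np.array(log_terms) - max(log_terms))
        return terms / terms.sum()


@dataclass(frozen=True)
class BufferMixture:
    """Volumes of the two stocks (plus optional water) forming one buffer."""

    phosphate_ml: float
    citrate_ml: float
    water_ml: float = 0.0
    phosphate_stock_m: float = PHOSPHATE_STOCK_M
    citrate_stock_m: float = CITRATE_STOCK_M
    temperature_c: float = 25.0
    activity_correction: bool = False

    def __post_init__(self):
        if min(self.phosphate_ml, self.citrate_ml, self.water_ml) < 0:
            raise ValueError("volumes must be >= 0")
        if self.total_ml <= 0:
            raise ValueError("total volume must be > 0")

    @property
    def total_ml(self) -> float:
        return self.phosphate_ml + self.citrate_ml + self.water_ml

    def species(self) -> list[AcidSpecies]:
        tot = self.total_ml
        return [
            AcidSpecies(
                "phosphoric acid",
                self.phosphate_stock_m * self.phosphate_ml / tot,
                PHOSPHORIC_ACID_PKAS,
                counterion_charge=2,  # disodium salt: 2 Na+ per formula unit
            ),
            AcidSpecies(
                "citric acid",
                self.citrate_stock_m * self.citrate_ml / tot,
                CITRIC_ACID_PKAS,
                counterion_charge=0,
            ),
        ]


@dataclass(frozen=True)
class BufferRecipe:
    target_ph: float
    phosphate_ml: float
    citrate_ml: float
    achieved_ph: float
    residual: float  # achieved - target


def _davies_log_gamma(z: int, ionic_strength: float) -> float:
    """log10 activity coefficient for charge z (Davies equation)."""
    if ionic_strength <= 0:
        return 0.0
    s = math.sqrt(ionic_strength)
    return -DAVIES_A * z * z * (s / (1.0 + s) - 0.3 * ionic_strength)


def _pka_shifts(species: AcidSpecies, ionic_strength: float) -> list[float]:
    """Shift thermodynamic pKa to the concentration (conditional) scale.

    For step HA(z) -> A(z-1) + H+:  pKa' = pKa + logG(A) + logG(H) - logG(HA),
    with logG from Davies.  Shifts are negative, so conditional acids are
    stronger at finite ionic strength.
    """
    shifts = []
    z_ha = species.charge_fully_protonated
    for i in range(len(species.pkas)):
        z_a = z_ha - (i + 1)
        shift = (
            _davies_log_gamma(z_a, ionic_strength)
            + _davies_log_gamma(1, ionic_strength)
            - _davies_log_gamma(z_ha - i, ionic_strength)
        )
        shifts.append(shift)
    return shifts


def _charge_balance(ph: float, species: list[AcidSpecies], ionic_strength: float) -> float:
    """Net charge (eq/L) at a given pH; positive when too acidic.

    pH is taken on the concentration scale (pH = -log10 [H+]), the
    constant-ionic-medium convention: activity effects enter only through
    the Davies-conditional equilibrium constants.
    """
    log_gamma_1 = _davies_log_gamma(1, ionic_strength)
    h = 10.0 ** (-ph)
    pkw_cond = PKW + 2.0 * log_gamma_1
    oh = 10.0 ** (-pkw_cond) / h
    net = h - oh
    for sp in species:
        net += sp.concentration * sp.counterion_charge
        alphas = sp.speciation(h, _pka_shifts(sp, ionic_strength))
        charges = sp.charge_fully_protonated - np.arange(len(alphas))
        net += sp.concentration * float(np.dot(alphas, charges))
    return net


def _ionic_strength(ph: float, species: list[AcidSpecies], ionic_strength: float) -> float:
    log_gamma_1 = _davies_log_gamma(1, ionic_strength)
    h = 10.0 ** (-ph)
    oh = 10.0 ** (-(PKW + 2.0 * log_gamma_1)) / h
    total = h + oh
    for sp in species:
        total += sp.concentration * sp.counterion_charge  # monovalent Na+
        alphas = sp.speciation(h, _pka_shifts(sp, ionic_strength))
        charges = sp.charge_fully_protonated - np.arange(len(alphas))
        total += sp.concentration * float(np.dot(alphas, charges**2))
    return 0.5 * total


def _solve_at_ionic_strength(species: list[AcidSpecies], ionic_strength: float) -> float:
    """Bisection on the charge balance over pH in [0, 14] to < 1e-12 eq/L."""
    lo, hi = 0.0, 14.0
    f_lo = _charge_balance(lo, species, ionic_strength)
    f_hi = _charge_balance(hi, species, ionic_strength)
    if f_lo < 0 or f_hi > 0:
        raise ValueError(
            "charge balance has no sign change on pH [0, 14]; check species definitions"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _charge_balance(mid, species, ionic_strength)
        if abs(f_mid) < 1e-12 and hi - lo < 1e-9:
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def solve_ph(mix: BufferMixture) -> float:
    """Equilibrium pH of a citrate-phosphate mixture.

    With ``activity_correction`` the Davies model is iterated: solve, update
    ionic strength from the resulting speciation, re-solve, until the pH
    moves by < 1e-6.
    """
    species = mix.species()
    ionic = 0.0
    ph = _solve_at_ionic_strength(species, ionic)
    if not mix.activity_correction:
        return ph
    for _ in range(100):
        ionic = _ionic_strength(ph, species, ionic)
        new_ph = _solve_at_ionic_strength(species, ionic)
        if abs(new_ph - ph) < 1e-6:
            return new_ph
        ph = new_ph
    return ph


def achievable_span(
    total_ml: float = 20.0, activity_correction: bool = True
) -> tuple[float, float]:
    """pH endpoints: pure citrate stock and pure phosphate stock."""
    lo = solve_ph(
        BufferMixture(0.0, total_ml, activity_correction=activity_correction)
    )
    hi = solve_ph(
        BufferMixture(total_ml, 0.0, activity_correction=activity_correction)
    )
    return lo, hi


def design_recipe(
    target_ph: float,
    total_ml: float = 20.0,
    activity_correction: bool = True,
    tol: float = 1e-4,
) -> BufferRecipe:
    """Volumes of the two stocks whose model pH equals the target.

    The solved pH is strictly increasing in the phosphate volume fraction
    (phosphate is the basic component), so a 1-D bracketed root find on the
    fraction suffices.
    """
    lo, hi = achievable_span(total_ml, activity_correction)
    if not (lo <= target_ph <= hi):
        raise ValueError(
            f"target pH {target_ph} outside achievable span [{lo:.2f}, {hi:.2f}] "
            "of the two-stock system"
        )

    def f(frac: float) -> float:
        mix = BufferMixture(
            frac * total_ml, (1.0 - frac) * total_ml, activity_correction=activity_correction
        )
        return solve_ph(mix) - target_ph

    frac = brentq(f, 0.0, 1.0, xtol=1e-8)
    achieved = f(frac) + target_ph
    assert abs(achieved - target_ph) < tol
    return BufferRecipe(
        target_ph=target_ph,
        phosphate_ml=frac * total_ml,
        citrate_ml=(1.0 - frac) * total_ml,
        achieved_ph=achieved,
        residual=achieved - target_ph,
    )


def design_series(
    targets: Sequence[float] = tuple(CITRATE_PHOSPHATE_SERIES),
    total_ml: float = 20.0,
    activity_correction: bool = True,
) -> list[BufferRecipe]:
    """Design the full buffer series (default: the twelve standard targets)."""
    return [design_recipe(t, total_ml, activity_correction) for t in targets]


def stock_mass(concentration_m: float, volume_l: float, molar_mass: float) -> float:
    """Grams of solid to weigh: c * V * M, rounded half-up to 3 decimals.

    Decimal arithmetic keeps the bench convention (5.2535 -> 5.254) free of
    binary-float round-half-to-even surprises.
    """
    if min(concentration_m, volume_l, molar_mass) < 0:
        raise ValueError("arguments must be >= 0")
    from decimal import ROUND_HALF_UP, Decimal

    grams = Decimal(str(concentration_m)) * Decimal(str(volume_l)) * Decimal(str(molar_mass))
    return float(grams.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def dilution(c_stock: float, v_stock: float, v_total: float) -> float:
    """Concentration after diluting v_stock of stock into v_total.

    Units cancel: any consistent concentration and volume units work.
    """
    if v_stock <= 0:
        raise ValueError("stock volume must be > 0")
    if v_total < v_stock:
        raise ValueError(f"total volume {v_total} < stock volume {v_stock}")
    return c_stock * v_stock / v_total
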