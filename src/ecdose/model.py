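"""Thermodynamic model of a nuclear-receptor-regulated promoter.

The model describes transcription of a gene controlled by one or more
ecdysone response elements (EREs), each permanently occupied by the
ecdysone receptor (EcR), together with an optional constitutive
enhancer or silencer element. Transcriptional activity is proportional
to the equilibrium probability that the transcriptional machinery (TM)
is recruited to the promoter.

Each DNA-bound receptor is in one of three states with statistical
weights

=================  ==============  =======================
state              weight          TM-affinity factor
=================  ==============  =======================
free (neutral)     1               1
corepressor-bound  kappa_R_bar     C_ER  (< 1, repressing)
ligand-bound       E / K_E         C_EA  (> 1, activating)
=================  ==============  =======================

where ``E`` is the hormone (20-hydroxy-ecdysone, "20E") concentration in
nM and ``K_E`` the ligand half-saturation constant. The TM binds the
promoter with basal weight ``kappa_P``, multiplied by the constitutive
element coefficient ``C_T`` (enhancer > 1, silencer < 1) and by the
state factor of every DNA-bound receptor; ``omega`` adds a pairwise
cooperativity factor between ligand-bound receptors.

For a single ERE the TM occupancy admits the closed form used
throughout::

    P(bound)  = kappa_P * C_T * chi(E) / (1 + kappa_P * C_T * chi(E))
    chi(E)    = 1 + (C_ER - 1) * P_rep(E) + (C_EA - 1) * P_act(E)

and the activity normalized to its saturating-ligand value is::

    A(E)/Amax = (chi/C_EA) * (1 + kappa_P*C_T*C_EA) / (1 + kappa_P*C_T*chi)

A brute-force partition-function enumeration over all joint TM x
receptor states is provided as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import product
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DEFAULT_DOSES",
    "ReceptorParams",
    "PromoterArchitecture",
    "SpongeSpec",
    "DoseResponseProfile",
    "ResponseFeatures",
    "receptor_probabilities",
    "chi",
    "bound_probability",
    "normalized_activity",
    "multi_ere_activity",
    "brute_force_activity",
    "predicted_fluorescence",
    "conditional_ligand_occupancy",
    "sponge_activity",
    "response_features",
    "half_activation_dose",
    "effective_hill_coefficient",
]

#: The study's hormone dose design, in nM.
DEFAULT_DOSES: tuple[float, ...] = (0.0, 20.0, 200.0, 2000.0)

#: Hard cap for state enumeration (2 * 3**n joint states).
MAX_ENUMERATED_SITES = 8


@dataclass(frozen=True)
class ReceptorParams:
    """Receptor-level ensemble producing P_act(E) and P_rep(E).

    Parameters
    ----------
    kappa_R_bar
        Dimensionless statistical weight of the corepressor-bound state
        (corepressor concentration x affinity; the corepressor pool is
        assumed constant across doses).
    K_E
        Ligand half-saturation constant in nM; the ligand-bound state
        carries weight ``E / K_E``.
    """

    kappa_R_bar: float = 1.0
    K_E: float = 65.0

    def __post_init__(self) -> None:
        if self.kappa_R_bar < 0:
            raise ValueError(f"kappa_R_bar must be >= 0, got {self.kappa_R_bar}")
        if self.K_E <= 0:
            raise ValueError(f"K_E must be > 0, got {self.K_E}")


@dataclass(frozen=True)
class PromoterArchitecture:
    """Regulatory layout of one gene or reporter construct.

    ``n_ere = 0`` encodes mutated-ERE controls, which retain the
    constitutive element but receive no receptor input. ``omega`` is the
    pairwise cooperativity factor between ligand-bound receptors
    (``omega = 1``: independent sites). ``k_T`` and ``baseline_offset``
    map TM occupancy to fluorescence intensity (arbitrary units).
    """

    n_ere: int = 1
    C_ER: float = 0.1
    C_EA: float = 10.0
    C_T: float = 1.0
    kappa_P: float = 0.1
    k_T: float = 1.0
    omega: float = 1.0
    baseline_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_ere < 0 or int(self.n_ere) != self.n_ere:
            raise ValueError(f"n_ere must be a nonnegative integer, got {self.n_ere}")
        if self.C_ER <= 0 or self.C_EA <= 0 or self.C_T <= 0:
            raise ValueError("cooperativity coefficients C_ER, C_EA, C_T must be > 0")
        if self.kappa_P <= 0:
            raise ValueError(f"kappa_P must be > 0, got {self.kappa_P}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")


@dataclass(frozen=True)
class SpongeSpec:
    """A non-DNA-binding receptor fragment titrating a shared cofactor pool.

    ``sponge_weight`` is the dimensionless concentration x affinity of the
    fragment for the pool; ``target`` selects which pool it sequesters.
    ``sponge_weight = 0`` reproduces the sponge-free model exactly.
    """

    sponge_weight: float = 0.0
    target: Literal["corepressor", "ligand"] = "corepressor"

    def __post_init__(self) -> None:
        if self.sponge_weight < 0:
            raise ValueError(f"sponge_weight must be >= 0, got {self.sponge_weight}")
        if self.target not in ("corepressor", "ligand"):
            raise ValueError(f"unknown sponge target {self.target!r}")


def _check_doses(E) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("hormone concentration E must be >= 0")
    return E


def receptor_probabilities(E, rp: ReceptorParams):
    """Probabilities that free EcR is ligand-activated / corepressed.

    First-order (Hill coefficient 1) in E::

        P_act = (E/K_E) / (1 + kappa_R_bar + E/K_E)
        P_rep = kappa_R_bar / (1 + kappa_R_bar + E/K_E)
    """
    E = _check_doses(E)
    e = E / rp.K_E
    z = 1.0 + rp.kappa_R_bar + e
    return e / z, rp.kappa_R_bar / z


def chi(E, rp: ReceptorParams, C_ER: float, C_EA: float):
    """Average statistical weight a DNA-bound EcR adds to the TM-bound state."""
    if C_ER <= 0 or C_EA <= 0:
        raise ValueError("C_ER and C_EA must be > 0")
    p_act, p_rep = receptor_probabilities(E, rp)
    return 1.0 + (C_ER - 1.0) * p_rep + (C_EA - 1.0) * p_act


def _bound_weight_ratio(E, arch: PromoterArchitecture, rp: ReceptorParams):
    """Z_bound / (kappa_P C_T Z_unbound), i.e. the average receptor factor.

    Closed form via the binomial sum over the number m of ligand-bound
    sites; written in saturating-safe variables q = e/(1+kR+e) and
    r = 1/(1+kR+e) so that E -> inf poses no overflow.
    """
    E = _check_doses(E)
    e = E / rp.K_E
    z = 1.0 + rp.kappa_R_bar + e
    q = e / z
    r = (1.0 + rp.kappa_R_bar * arch.C_ER) / z
    n = arch.n_ere
    total = np.zeros_like(np.asarray(E, dtype=float))
    for m in range(n + 1):
        pair_factor = float(arch.omega) ** (m * (m - 1) // 2)
        total = total + (
            math.comb(n, m) * pair_factor * (q * arch.C_EA) ** m * r ** (n - m)
        )
    return total if n > 0 else np.ones_like(np.asarray(E, dtype=float))


def bound_probability(E, arch: PromoterArchitecture, rp: ReceptorParams):
    """Absolute TM occupancy P(machinery bound) at hormone dose E."""
    w = arch.kappa_P * arch.C_T * _bound_weight_ratio(E, arch, rp)
    return w / (1.0 + w)


_bound_probability = bound_probability


def _saturating_bound_probability(arch: PromoterArchitecture) -> float:
    """TM occupancy in the saturating-ligand limit (all sites ligand-bound)."""
    n = arch.n_ere
    w = (
        arch.kappa_P
        * arch.C_T
        * arch.C_EA**n
        * float(arch.omega) ** (n * (n - 1) // 2)
    )
    return w / (1.0 + w)


def normalized_activity(E, arch: PromoterArchitecture, rp: ReceptorParams):
    """Normalized activity A(E)/Amax of a single-ERE gene (closed form).

    Equals ``(chi/C_EA) * (1 + kP*CT*C_EA) / (1 + kP*CT*chi)``; use
    :func:`multi_ere_activity` for ``n_ere != 1``.
    """
    if arch.n_ere != 1:
        raise ValueError(
            f"normalized_activity is the single-ERE closed form (n_ere=1); "
            f"got n_ere={arch.n_ere}, use multi_ere_activity"
        )
    x = chi(E, rp, arch.C_ER, arch.C_EA)
    kct = arch.kappa_P * arch.C_T
    return (x / arch.C_EA) * (1.0 + kct * arch.C_EA) / (1.0 + kct * x)


def multi_ere_activity(E, arch: PromoterArchitecture, rp: ReceptorParams):
    """Normalized activity for any number of EREs with cooperativity omega.

    With ``omega = 1`` the receptor factor reduces to chi(E)**n_ere
    (independent sites); ``omega > 1`` steepens the dose response.
    ``n_ere = 0`` returns a curve identically 1 (activity constant in E).
    """
    if arch.n_ere < 0:
        raise ValueError("n_ere must be >= 0")
    p = _bound_probability(E, arch, rp)
    p_inf = _saturating_bound_probability(arch)
    if p_inf == 0.0:
        raise ValueError(
            "saturating-ligand anchor vanishes (omega=0 with n_ere>=2); "
            "compare unnormalized occupancy via bound_probability instead"
        )
    return p / p_inf


_STATE_WEIGHTS = ("free", "corepressor", "ligand")


def _enumerate_bound_probability(
    e: float, arch: PromoterArchitecture, rp: ReceptorParams
) -> float:
    """Partition-function enumeration of all 2 * 3**n joint states."""
    n = arch.n_ere
    site_w = (1.0, rp.kappa_R_bar, e)  # receptor state weights
    site_c = (1.0, arch.C_ER, arch.C_EA)  # TM-affinity factors
    z_unbound = 0.0
    z_bound = 0.0
    for states in product(range(3), repeat=n):
        w = 1.0
        cw = 1.0
        for s in states:
            w *= site_w[s]
            cw *= site_c[s]
        m = sum(1 for s in states if s == 2)
        z_unbound += w
        z_bound += (
            arch.kappa_P
            * arch.C_T
            * w
            * cw
            * float(arch.omega) ** (m * (m - 1) // 2)
        )
    return z_bound / (z_unbound + z_bound)


def brute_force_activity(E, arch: PromoterArchitecture, rp: ReceptorParams):
    """Independent oracle: normalized activity by full state enumeration.

    Enumerates every joint {TM bound/unbound} x {receptor state per ERE}
    configuration, multiplies Boltzmann weights, and normalizes TM
    occupancy by its saturating-ligand value (obtained from the same
    enumeration restricted to all-ligand-bound receptor states, with the
    diverging ligand weights cancelled).
    """
    if arch.n_ere > MAX_ENUMERATED_SITES:
        raise ValueError(
            f"enumeration refused for n_ere={arch.n_ere} "
            f"(> {MAX_ENUMERATED_SITES}; state count 2*3**n)"
        )
    E = _check_doses(E)
    n = arch.n_ere
    # Saturating limit: only all-ligand configurations survive; e**n cancels.
    w_inf = (
        arch.kappa_P
        * arch.C_T
        * arch.C_EA**n
        * float(arch.omega) ** (n * (n - 1) // 2)
    )
    p_inf = w_inf / (1.0 + w_inf)
    scalar = np.ndim(E) == 0
    out = np.array(
        [
            _enumerate_bound_probability(ei / rp.K_E, arch, rp) / p_inf
            for ei in np.atleast_1d(E)
        ]
    )
    return float(out[0]) if scalar else out


def predicted_fluorescence(E, arch: PromoterArchitecture, rp: ReceptorParams):
    """Reporter intensity in a.u.: ``k_T * P(TM bound) + baseline_offset``.

    Mutated-ERE controls (``n_ere = 0``) give the constant
    ``k_T * kP*CT / (1 + kP*CT) + offset``.
    """
    return arch.k_T * _bound_probability(E, arch, rp) + arch.baseline_offset


def conditional_ligand_occupancy(E, arch: PromoterArchitecture, rp: ReceptorParams):
    """Probability that a DNA-bound EcR is ligand-bound (activating state).

    Marginalized over TM occupancy. Because TM binding and ligand binding
    stabilize each other through C_EA, this exceeds the free-receptor
    P_act(E) and increases with C_T at fixed E > 0 — the thermodynamic
    "effective affinity" boost conferred by a constitutive enhancer.
    """
    if arch.n_ere < 1:
        raise ValueError("conditional_ligand_occupancy requires n_ere >= 1")
    if arch.n_ere > MAX_ENUMERATED_SITES:
        raise ValueError(f"enumeration refused for n_ere={arch.n_ere}")
    E = _check_doses(E)
    scalar = np.ndim(E) == 0

    def one(e: float) -> float:
        n = arch.n_ere
        site_w = (1.0, rp.kappa_R_bar, e)
        site_c = (1.0, arch.C_ER, arch.C_EA)
        z = 0.0
        z_lig = 0.0
        for states in product(range(3), repeat=n):
            w = 1.0
            cw = 1.0
            for s in states:
                w *= site_w[s]
                cw *= site_c[s]
            m = sum(1 for s in states if s == 2)
            pair = float(arch.omega) ** (m * (m - 1) // 2)
            tot = w + arch.kappa_P * arch.C_T * w * cw * pair
            z += tot
            if states[0] == 2:  # the tracked receptor is ligand-bound
                z_lig += tot
        return z_lig / z

    out = np.array([one(ei / rp.K_E) for ei in np.atleast_1d(E)])
    return float(out[0]) if scalar else out


def _free_pool_weight(total: float, sponge_weight: float) -> float:
    """Free cofactor weight after mass-action sequestration by the sponge.

    Conservation with unit-affinity sponge saturation,
    ``x + s*x/(1+x) = total``, solved exactly (positive root of the
    quadratic). ``s = 0`` returns ``total`` unchanged.
    """
    if total == 0.0 or sponge_weight == 0.0:
        return total
    b = 1.0 + sponge_weight - total
    x = 0.5 * (-b + math.sqrt(b * b + 4.0 * total))
    if not np.isfinite(x) or x < 0:
        raise ArithmeticError(
            f"sponge conservation solve failed: total={total}, "
            f"sponge_weight={sponge_weight}, root={x}"
        )
    return x


def sponge_activity(
    E, arch: PromoterArchitecture, rp: ReceptorParams, sponge: SpongeSpec
):
    """Normalized activity with part of a cofactor pool titrated away.

    The sponged pool's statistical weight is replaced by the free weight
    solving the mass-action conservation equation; the standard model is
    then evaluated with the reduced pool. Sequestering the corepressor
    de-represses the promoter at low hormone (baseline rises toward the
    neutral-receptor level as sponge_weight grows).
    """
    if sponge.sponge_weight == 0.0:
        return multi_ere_activity(E, arch, rp)
    if sponge.target == "corepressor":
        free = _free_pool_weight(rp.kappa_R_bar, sponge.sponge_weight)
        return multi_ere_activity(E, arch, replace(rp, kappa_R_bar=free))
    # ligand pool: titrate per dose, then evaluate at the free concentration
    E = _check_doses(E)
    scalar = np.ndim(E) == 0
    e_free = np.array(
        [
            _free_pool_weight(ei / rp.K_E, sponge.sponge_weight)
            for ei in np.atleast_1d(E)
        ]
    )
    out = multi_ere_activity(e_free * rp.K_E, arch, rp)
    return float(np.atleast_1d(out)[0]) if scalar else out


@dataclass(frozen=True)
class DoseResponseProfile:
    """Ordered (dose -> value) vector for one gene or reporter."""

    doses: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.values):
            raise ValueError("doses and values must have equal length")
        d = np.asarray(self.doses, dtype=float)
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("doses must be nonnegative and strictly increasing")


@dataclass(frozen=True)
class ResponseFeatures:
    fold_change: float
    delta_ratio: float
    pseudocount: float


def response_features(
    profile: DoseResponseProfile, pseudocount: float | None = None
) -> ResponseFeatures:
    """Overall fold change and delta-ratio of a 4-dose profile.

    On the default grid {0, 20, 200, 2000} nM::

        delta_ratio = (x2000 - x20) / (x20 - x0 + eps)
        fold_change = (x2000 + eps) / (x0 + eps)

    ``eps`` defaults to 1e-6 of the profile maximum; with ``eps = 0`` a
    zero-baseline gene has infinite fold change.
    """
    if tuple(profile.doses) != DEFAULT_DOSES:
        raise ValueError(
            f"response_features requires the dose grid {DEFAULT_DOSES}, "
            f"got {tuple(profile.doses)}"
        )
    x0, x20, _, x2000 = profile.values
    eps = 1e-6 * max(profile.values) if pseudocount is None else float(pseudocount)
    delta = (x2000 - x20) / (x20 - x0 + eps)
    with np.errstate(divide="ignore"):
        fold = (x2000 + eps) / (x0 + eps) if (x0 + eps) != 0 else math.inf
    return ResponseFeatures(fold_change=float(fold), delta_ratio=float(delta), pseudocount=eps)


def half_activation_dose(
    arch: PromoterArchitecture,
    rp: ReceptorParams,
    e_max: float = 1e7,
) -> float:
    """Dose at which activity reaches half its dynamic range.

    Root of ``A(E) = (A(0) + 1) / 2`` (the normalized curve saturates at 1).
    """
    a0 = float(multi_ere_activity(0.0, arch, rp))
    target = 0.5 * (a0 + 1.0)

    def f(E: float) -> float:
        return float(multi_ere_activity(E, arch, rp)) - target

    if f(e_max) < 0:
        raise ValueError("activity does not reach half its dynamic range below e_max")
    return float(brentq(f, 0.0, e_max, xtol=1e-9, rtol=1e-12))


def effective_hill_coefficient(
    arch: PromoterArchitecture,
    rp: ReceptorParams,
    doses: Sequence[float] | None = None,
) -> float:
    """Maximum logarithmic slope max_E d log A / d log E of the dose response."""
    if doses is None:
        doses = np.logspace(-2, 5, 400) * rp.K_E / 65.0
    E = np.asarray(doses, dtype=float)
    a = np.asarray(multi_ere_activity(E, arch, rp), dtype=float)
    slopes = np.diff(np.log(a)) / np.diff(np.log(E))
    return float(np.max(slopes))
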