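"""Joint fitting of the promoter model to multi-construct reporter data.

Several reporter constructs (minimal ERE reporter, enhancer and silencer
combinations, mutated-ERE controls) share one receptor ensemble and one
promoter machinery; each constitutive element contributes its own C_T.
All constructs are fitted together by bounded nonlinear least squares on
replicate-mean intensities, from Latin-hypercube multi-starts, with
strictly positive parameters handled in log10 space.

The corepressor weight kappa_R_bar is fixed (default 1) during fitting:
the receptor layer chi(E) = (u*K_E + E*C_EA) / (v*K_E + E) with
u = 1 + kappa_R_bar*C_ER and v = 1 + kappa_R_bar exposes only three
identifiable combinations of the four receptor parameters, so one must
be pinned for C_ER and K_E to be individually meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.stats import qmc

from .model import PromoterArchitecture, ReceptorParams, chi, predicted_fluorescence

__all__ = [
    "ConstructMeta",
    "ReporterDataset",
    "FitResult",
    "fit_joint",
    "derepression_threshold",
    "identifiability_report",
]


@dataclass(frozen=True)
class ConstructMeta:
    """Regulatory metadata for one reporter construct.

    ``ct_label`` names the constitutive element whose C_T this construct
    carries; constructs sharing a label (an element and its mutated-ERE
    control) share the fitted C_T. ``None`` means no element (C_T = 1).
    """

    n_ere: int
    element: Literal["none", "enhancer", "silencer"] = "none"
    ct_label: str | None = None

    @property
    def has_functional_ere(self) -> bool:
        return self.n_ere > 0


@dataclass
class ReporterDataset:
    """Tidy reporter fluorescence measurements plus construct metadata.

    ``data`` columns: construct_id, dose_nM, replicate, intensity.
    """

    data: pd.DataFrame
    constructs: dict[str, ConstructMeta]

    def __post_init__(self) -> None:
        required = {"construct_id", "dose_nM", "replicate", "intensity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"reporter data missing columns {sorted(missing)}")
        if (self.data["intensity"] < 0).any():
            raise ValueError("intensities must be >= 0")
        unknown = set(self.data["construct_id"]) - set(self.constructs)
        if unknown:
            raise ValueError(f"constructs without metadata: {sorted(unknown)}")
        for cid, grp in self.data.groupby("construct_id"):
            if grp["dose_nM"].nunique() < 2:
                raise ValueError(f"construct {cid!r} has < 2 distinct doses")

    def replicate_means(self) -> pd.DataFrame:
        """Mean intensity per (construct, dose), sorted deterministically."""
        out = (
            self.data.groupby(["construct_id", "dose_nM"], sort=True)["intensity"]
            .mean()
            .reset_index()
        )
        return out

    @property
    def ct_labels(self) -> list[str]:
        labels = {m.ct_label for m in self.constructs.values() if m.ct_label}
        return sorted(labels)


#: Default fitting bounds (log10 space is used internally).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "kappa_P": (1e-4, 10.0),
    "K_E": (0.1, 1e4),
    "C_ER": (1e-3, 1.0),
    "C_EA": (1.0, 1e3),
    "C_T": (1e-3, 1e3),
}


@dataclass
class FitResult:
    """Best-fit shared parameters, per-element C_T values and diagnostics."""

    params: dict[str, float]  # kappa_P, kappa_R_bar, K_E, C_ER, C_EA, k_T, offset
    ct: dict[str, float]  # ct_label -> C_T
    objective: float
    starts: list[dict] = field(default_factory=list)
    seed: int | None = None
    n_starts: int = 0
    success: bool = True

    def construct_params(
        self, meta: ConstructMeta
    ) -> tuple[PromoterArchitecture, ReceptorParams]:
        ct = self.ct[meta.ct_label] if meta.ct_label else 1.0
        arch = PromoterArchitecture(
            n_ere=meta.n_ere,
            C_ER=self.params["C_ER"],
            C_EA=self.params["C_EA"],
            C_T=ct,
            kappa_P=self.params["kappa_P"],
            k_T=self.params["k_T"],
            baseline_offset=self.params["offset"],
        )
        rp = ReceptorParams(self.params["kappa_R_bar"], self.params["K_E"])
        return arch, rp

    def predict(self, meta: ConstructMeta, doses) -> np.ndarray:
        arch, rp = self.construct_params(meta)
        return np.asarray(predicted_fluorescence(doses, arch, rp))


def _pack_names(data: ReporterDataset, fit_offset: bool, fit_kappa_R: bool):
    names = ["kappa_P", "K_E", "C_ER", "C_EA", "k_T"]
    if fit_kappa_R:
        names.append("kappa_R_bar")
    names += [f"C_T[{lab}]" for lab in data.ct_labels]
    if fit_offset:
        names.append("offset")
    return names


def _bounds_for(name: str, data_max: float, bounds: Mapping[str, tuple[float, float]]):
    if name.startswith("C_T["):
        return bounds["C_T"]
    if name == "k_T":
        return (1e-2 * data_max, 1e2 * data_max)
    if name == "kappa_R_bar":
        return (1e-3, 1e3)
    if name == "offset":
        return (1e-6 * data_max, data_max)
    return bounds[name]


def _unpack(
    x: np.ndarray,
    names: Sequence[str],
    kappa_R_fixed: float,
) -> tuple[dict[str, float], dict[str, float]]:
    vals = dict(zip(names, 10.0**x))
    ct = {
        name[4:-1]: v for name, v in vals.items() if name.startswith("C_T[")
    }
    params = {
        "kappa_P": vals["kappa_P"],
        "K_E": vals["K_E"],
        "C_ER": vals["C_ER"],
        "C_EA": vals["C_EA"],
        "k_T": vals["k_T"],
        "kappa_R_bar": vals.get("kappa_R_bar", kappa_R_fixed),
        "offset": vals.get("offset", 0.0),
    }
    return params, ct


def _residuals_factory(data: ReporterDataset, names, kappa_R_fixed: float):
    means = data.replicate_means()
    data_max = float(means["intensity"].max())
    floor = 1e-3 * data_max  # guards relative residuals of near-silent points
    groups = []
    for cid, grp in means.groupby("construct_id", sort=True):
        meta = data.constructs[cid]
        groups.append((meta, grp["dose_nM"].to_numpy(), grp["intensity"].to_numpy()))

    def residuals(x: np.ndarray) -> np.ndarray:
        params, ct = _unpack(x, names, kappa_R_fixed)
        rp = ReceptorParams(params["kappa_R_bar"], params["K_E"])
        res = []
        for meta, doses, obs in groups:
            arch = PromoterArchitecture(
                n_ere=meta.n_ere,
                C_ER=params["C_ER"],
                C_EA=params["C_EA"],
                C_T=ct[meta.ct_label] if meta.ct_label else 1.0,
                kappa_P=params["kappa_P"],
                k_T=params["k_T"],
                baseline_offset=params["offset"],
            )
            pred = np.asarray(predicted_fluorescence(doses, arch, rp))
            res.append((obs - pred) / (obs + floor))
        return np.concatenate(res)

    return residuals, data_max


def fit_joint(
    data: ReporterDataset,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 32,
    seed: int = 0,
    kappa_R_bar: float = 1.0,
    fit_kappa_R: bool = False,
    fit_offset: bool = False,
) -> FitResult:
    """Jointly estimate shared parameters and per-element C_T values.

    Least squares on replicate means with residuals scaled by the
    observed intensity (multiplicative-noise weighting), log10
    parameterization, bounded trust-region solves from ``n_starts``
    Latin-hypercube starting points. Deterministic for a given seed; the
    best start wins, ties broken by start index.
    """
    if len(data.constructs) < 2:
        raise ValueError("joint fitting requires >= 2 constructs")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    names = _pack_names(data, fit_offset, fit_kappa_R)
    residuals, data_max = _residuals_factory(data, names, kappa_R_bar)
    lo = np.log10([_bounds_for(n, data_max, b)[0] for n in names])
    hi = np.log10([_bounds_for(n, data_max, b)[1] for n in names])

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    x0s = [0.5 * (lo + hi)] + list(lo + sampler.random(n_starts - 1) * (hi - lo))

    starts: list[dict] = []
    best = None
    for i, x0 in enumerate(x0s):
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
            )
            rec = {
                "start": i,
                "cost": float(sol.cost),
                "success": bool(sol.success),
                "nfev": int(sol.nfev),
                "message": sol.status,
            }
            if sol.success and (best is None or sol.cost < best[0] - 0.0):
                best = (float(sol.cost), i, sol)
        except Exception as exc:  # pragma: no cover - defensive
            rec = {"start": i, "cost": np.inf, "success": False, "error": str(exc)}
        starts.append(rec)

    if best is None:
        raise RuntimeError(
            "all optimization starts failed to converge; diagnostics: "
            + "; ".join(str(s) for s in starts)
        )
    _, _, sol = best
    params, ct = _unpack(sol.x, names, kappa_R_bar)
    return FitResult(
        params=params,
        ct=ct,
        objective=float(2.0 * sol.cost),  # sum of squared residuals
        starts=starts,
        seed=seed,
        n_starts=n_starts,
        success=True,
    )


def derepression_threshold(fit: FitResult | Mapping[str, float], e_max: float = 1e6) -> float:
    """Hormone dose at which chi(E) crosses 1 (repression lifted).

    Below the threshold the average DNA-bound receptor represses
    (chi < 1); above it, it activates. Returns 0 when C_ER >= 1 or the
    corepressor weight is 0 (nothing to lift); raises if chi never
    crosses 1 within ``e_max``.
    """
    params = fit.params if isinstance(fit, FitResult) else dict(fit)
    rp = ReceptorParams(params["kappa_R_bar"], params["K_E"])
    c_er, c_ea = params["C_ER"], params["C_EA"]
    if c_er >= 1.0 or rp.kappa_R_bar == 0.0:
        return 0.0

    def f(E: float) -> float:
        return float(chi(E, rp, c_er, c_ea)) - 1.0

    if f(e_max) <= 0.0:
        raise ValueError(
            f"chi(E) does not cross 1 within [0, {e_max}] nM (C_EA={c_ea})"
        )
    return float(brentq(f, 0.0, e_max, xtol=1e-9, rtol=1e-12))


def identifiability_report(
    data: ReporterDataset,
    fit: FitResult,
    n_points: int = 7,
    span: float = 4.0,
    flat_tol: float = 0.05,
    kappa_R_bar: float = 1.0,
    fit_kappa_R: bool = False,
) -> dict[str, dict]:
    """1-D profile of the objective around the optimum for each parameter.

    Each parameter is stepped over a log-symmetric grid (factor ``span``
    each way, clipped to bounds) while all others are re-optimized from
    the fitted optimum. A parameter is flagged ``flat`` when the profiled
    objective fails to rise (by ``flat_tol``, relative with an absolute
    floor) toward either end of the grid — the signature of a
    structurally unidentifiable direction such as k_T vs kappa_P on
    mutated-control-only data, where the ridge is one-sided because
    k_T must exceed the largest observed intensity.
    """
    fit_offset = fit.params.get("offset", 0.0) > 0
    names = _pack_names(data, fit_offset, fit_kappa_R)
    residuals, data_max = _residuals_factory(data, names, kappa_R_bar)
    b = DEFAULT_BOUNDS
    lo = np.log10([_bounds_for(n, data_max, b)[0] for n in names])
    hi = np.log10([_bounds_for(n, data_max, b)[1] for n in names])

    x_opt = []
    for n in names:
        if n.startswith("C_T["):
            x_opt.append(np.log10(fit.ct[n[4:-1]]))
        else:
            x_opt.append(np.log10(fit.params[n]))
    x_opt = np.asarray(x_opt)
    obj0 = float(np.sum(residuals(x_opt) ** 2))

    report: dict[str, dict] = {}
    for j, name in enumerate(names):
        grid = np.linspace(
            max(x_opt[j] - np.log10(span), lo[j]),
            min(x_opt[j] + np.log10(span), hi[j]),
            n_points,
        )
        profile = []
        for g in grid:
            free = [k for k in range(len(names)) if k != j]

            def sub(xf, g=g, free=free):
                x = x_opt.copy()
                x[free] = xf
                x[j] = g
                return residuals(x)

            sol = least_squares(
                sub,
                x_opt[free],
                bounds=(lo[free], hi[free]),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
            )
            profile.append(float(2.0 * sol.cost))
        # A direction is non-identifiable when the profiled objective fails
        # to rise toward either end of the grid (flat ridges may be
        # one-sided, e.g. k_T >= max intensity on control-only data).
        ref = min(min(profile), obj0)
        tol = flat_tol * max(ref, 1e-6)
        flat = (profile[0] - ref < tol) or (profile[-1] - ref < tol)
        report[name] = {
            "grid": 10.0**grid,
            "objective": np.asarray(profile),
            "flat": bool(flat),
        }
    return report
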