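"""Ground-truth-labeled synthetic inputs for the analysis pipeline.

Two generators:

* :func:`simulate_counts` builds a dose-response RNA-seq count matrix in
  which every gene's mean profile follows the thermodynamic promoter
  model. Genes come in three archetypes distinguished only by the
  constitutive-element strength C_T (default {5, 1, 0.1}), producing the
  high-baseline / intermediate / high-threshold cluster shapes. Counts
  are negative-binomial with variance mu + alpha * mu**2 around
  per-sample-scaled means.

* :func:`simulate_reporters` builds noisy fluorescence dose-response
  tables for a panel of synthetic reporter constructs (minimal ERE
  reporter, enhancer and silencer combinations, and a mutated-ERE
  control), for exercising the joint fit.

Shared receptor/promoter defaults are the parameter set the archetype
curves are illustrated with (kappa_P = 0.1, kappa_R_bar = 1, C_ER = 0.1,
C_EA = 10) plus K_E = 65 nM, which places the repression-to-activation
crossover near 5 nM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import ConstructMeta, ReporterDataset
from .model import (
    DEFAULT_DOSES,
    PromoterArchitecture,
    ReceptorParams,
    multi_ere_activity,
    predicted_fluorescence,
)
from .pipeline import CountMatrix

__all__ = [
    "SimulationSpec",
    "simulate_counts",
    "simulate_reporters",
    "DEFAULT_REPORTER_PANEL",
    "REPORTER_TRUTH",
    "REPORTER_DOSES",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for the synthetic count matrix."""

    n_genes_per_archetype: int = 100
    n_background_genes: int = 700  # flat, dose-independent genes
    archetype_ct: tuple[float, ...] = (5.0, 1.0, 0.1)
    kappa_R_bar: float = 1.0
    K_E: float = 65.0
    C_ER: float = 0.1
    C_EA: float = 10.0
    kappa_P: float = 0.1
    base_log_mean: float = math.log(1500.0)  # log-normal base expression
    base_log_sd: float = 0.6
    dispersion: float = 0.05  # NB: var = mu + dispersion * mu**2
    replicates: int = 3
    doses: tuple[float, ...] = DEFAULT_DOSES
    size_factor_log_sd: float = 0.15  # per-sample depth variation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.replicates < 1 or self.n_genes_per_archetype < 1:
            raise ValueError("replicates and n_genes_per_archetype must be >= 1")

    def receptor(self) -> ReceptorParams:
        return ReceptorParams(self.kappa_R_bar, self.K_E)

    def architecture(self, c_t: float) -> PromoterArchitecture:
        return PromoterArchitecture(
            n_ere=1,
            C_ER=self.C_ER,
            C_EA=self.C_EA,
            C_T=c_t,
            kappa_P=self.kappa_P,
        )


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with variance mu + alpha*mu**2; alpha = 0 is noise-free."""
    if alpha == 0.0:
        return np.rint(mu).astype(np.int64)
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mu)
    return rng.negative_binomial(n, p).astype(np.int64)


def simulate_counts(spec: SimulationSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Dose-response count matrix plus per-gene ground truth.

    Gene i at dose j has mean ``size_factor_j * base_i * A_i(E_j)`` where
    ``A_i`` is the model's normalized activity at that gene's archetype
    C_T. Flat background genes (archetype 0 in the truth table, activity
    1 at every dose) emulate the non-responsive majority of a real
    transcriptome and anchor the median-of-ratios normalization. Returns
    the count matrix (with sample sheet) and a truth table (archetype,
    C_T, base expression); archetypes 1..n follow ``archetype_ct``.
    """
    rng = np.random.default_rng(spec.seed)
    rp = spec.receptor()
    activities = {
        c_t: np.asarray(multi_ere_activity(np.asarray(spec.doses), spec.architecture(c_t), rp))
        for c_t in spec.archetype_ct
    }

    sample_ids, sample_rows = [], []
    for dose in spec.doses:
        for rep in range(1, spec.replicates + 1):
            sample_ids.append(f"d{int(dose)}_r{rep}")
            sample_rows.append({"dose_nM": float(dose), "replicate": rep})
    samples = pd.DataFrame(sample_rows, index=pd.Index(sample_ids, name="sample"))
    sf = np.exp(rng.normal(0.0, spec.size_factor_log_sd, size=len(sample_ids)))
    dose_idx = np.array(
        [list(spec.doses).index(samples.iloc[j]["dose_nM"]) for j in range(len(sample_ids))]
    )

    gene_ids, truth_rows, count_rows = [], [], []
    g = 0
    flat = np.ones(len(sample_ids))
    blocks = [(archetype, c_t, activities[c_t][dose_idx], spec.n_genes_per_archetype)
              for archetype, c_t in enumerate(spec.archetype_ct, start=1)]
    blocks.append((0, float("nan"), flat, spec.n_background_genes))
    for archetype, c_t, act, n_genes in blocks:
        for _ in range(n_genes):
            g += 1
            gid = f"g{g:04d}"
            base = rng.lognormal(spec.base_log_mean, spec.base_log_sd)
            mu = sf * base * act
            counts = _nb_sample(rng, mu, spec.dispersion)
            gene_ids.append(gid)
            count_rows.append(counts)
            truth_rows.append(
                {"gene": gid, "archetype": archetype, "C_T": c_t, "base": base}
            )

    counts = pd.DataFrame(
        np.vstack(count_rows), index=pd.Index(gene_ids, name="gene"), columns=sample_ids
    )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return CountMatrix(counts=counts, samples=samples), truth


# ---------------------------------------------------------------------------
# Reporter panel


#: Dose design used for reporter fitting studies (nM).
REPORTER_DOSES: tuple[float, ...] = (0.0, 5.0, 20.0, 100.0, 500.0, 2000.0)

#: Ground-truth shared parameters for the default panel (best-fit-like).
REPORTER_TRUTH: dict[str, float] = {
    "kappa_P": 0.03,
    "kappa_R_bar": 1.0,
    "K_E": 65.0,
    "C_ER": 0.1,
    "C_EA": 13.0,
    "k_T": 131.0,
    "offset": 0.0,
    "C_T[enhancer]": 2.0,
    "C_T[silencer]": 0.1,
}

#: Construct panel: minimal ERE reporter, enhancer and silencer
#: combinations, and the enhancer's mutated-ERE control (which pins the
#: ligand-independent level of the enhancer element).
DEFAULT_REPORTER_PANEL: dict[str, ConstructMeta] = {
    "10xERE": ConstructMeta(n_ere=1, element="none", ct_label=None),
    "3xGBE-10xERE": ConstructMeta(n_ere=1, element="enhancer", ct_label="enhancer"),
    "2xBrkS-10xERE": ConstructMeta(n_ere=1, element="silencer", ct_label="silencer"),
    "3xGBE-10xERE*": ConstructMeta(n_ere=0, element="enhancer", ct_label="enhancer"),
}


def _panel_architecture(
    meta: ConstructMeta, truth: dict[str, float]
) -> tuple[PromoterArchitecture, ReceptorParams]:
    c_t = truth[f"C_T[{meta.ct_label}]"] if meta.ct_label else 1.0
    arch = PromoterArchitecture(
        n_ere=meta.n_ere,
        C_ER=truth["C_ER"],
        C_EA=truth["C_EA"],
        C_T=c_t,
        kappa_P=truth["kappa_P"],
        k_T=truth["k_T"],
        baseline_offset=truth["offset"],
    )
    return arch, ReceptorParams(truth["kappa_R_bar"], truth["K_E"])


def simulate_reporters(
    panel: dict[str, ConstructMeta] | None = None,
    truth: dict[str, float] | None = None,
    sigma: float = 0.1,
    replicates: int = 3,
    doses: tuple[float, ...] = REPORTER_DOSES,
    seed: int = 0,
) -> ReporterDataset:
    """Noisy reporter fluorescence table: pred * (1 + N(0, sigma)).

    ``sigma = 0`` returns exact model curves. Intensities are clipped at
    zero (fluorescence cannot be negative).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    panel = dict(DEFAULT_REPORTER_PANEL if panel is None else panel)
    truth = dict(REPORTER_TRUTH if truth is None else truth)
    rng = np.random.default_rng(seed)
    records = []
    for cid in sorted(panel):
        arch, rp = _panel_architecture(panel[cid], truth)
        pred = np.asarray(predicted_fluorescence(np.asarray(doses), arch, rp))
        for rep in range(1, replicates + 1):
            noisy = pred * (1.0 + rng.normal(0.0, sigma, size=len(doses)))
            for dose, value in zip(doses, noisy):
                records.append(
                    {
                        "construct_id": cid,
                        "dose_nM": float(dose),
                        "replicate": rep,
                        "intensity": max(float(value), 0.0),
                    }
                )
    data = pd.DataFrame.from_records(records)
    return ReporterDataset(data=data, constructs=panel)
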