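"""Three-step comparative classification of transcripts between populations.

Per tissue, with individuals as biological replicates:

Step 1 — UETs: transcripts expressed (FPKM above a presence threshold,
default 0) in every sample of one population and exactly zero in every
sample of the other.  Transcripts not expressed in both populations are
excluded from the following steps.

Step 2 — EETs: within each population, every pair of individuals is tested
with the empirical-Bayes engine (one library per side); a transcript is an
EET for the population when it is called equally expressed (PPEE >= 1 - FDR)
in all pairwise comparisons.  The EET-both set is the intersection across
populations.

Step 3 — DETs: restricted to EET-both, the engine is fitted population A
versus population B (n individuals per side) and transcripts are called at
FDR < 0.05 with fold change > 1.5, with the over-expressed population
recorded as the direction.

The per-tissue mode matches the organ-wise result tables of such studies; a
"global" UET mode requiring presence in all tissues is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .abundance import ExpressionMatrix, fpkm, size_factors
from .ebde import call_de, call_ee, fit_eb
from .simulate import SampleDesign

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    pass


@dataclass
class TissueResult:
    uet_a: Set[str]
    uet_b: Set[str]
    eet_a: Set[str]
    eet_b: Set[str]
    eet_both: Set[str]
    det_table: pd.DataFrame  # index: transcript; PPDE, PPEE, FC, direction
    step_counts: Dict[str, int] = field(default_factory=dict)

    def check_invariants(self) -> None:
        det = set(self.det_table.index)
        assert det <= self.eet_both, "DET set must be within EET-both"
        assert not (self.uet_a & self.uet_b), "UET sets must be disjoint"
        assert not (det & (self.uet_a | self.uet_b)), "UETs cannot be DETs"


@dataclass
class PipelineResult:
    per_tissue: Dict[str, TissueResult]
    populations: Tuple[str, str]
    metadata: Dict[str, object] = field(default_factory=dict)

    def det_union(self) -> Set[str]:
        out: Set[str] = set()
        for res in self.per_tissue.values():
            out |= set(res.det_table.index)
        return out

    def uet_union(self, which: str) -> Set[str]:
        out: Set[str] = set()
        for res in self.per_tissue.values():
            out |= res.uet_a if which == "A" else res.uet_b
        return out


def _pop_columns(design: SampleDesign, tissue: Optional[str]) -> Tuple[List[str], List[str]]:
    pop_a, pop_b = design.populations
    cols_a = design.samples(population=pop_a, tissue=tissue)
    cols_b = design.samples(population=pop_b, tissue=tissue)
    if not cols_a or not cols_b:
        raise DesignError("both populations must be present")
    return cols_a, cols_b


def classify_uet(
    tissue_matrix: ExpressionMatrix,
    design: SampleDesign,
    tissue: Optional[str] = None,
    presence_eps: float = 0.0,
) -> Tuple[Set[str], Set[str]]:
    """Step 1: uniquely expressed transcripts for each population.

    A transcript is UET-A when its expression exceeds ``presence_eps`` in
    every population-A sample of the tissue (all tissues when ``tissue`` is
    None) and is exactly zero in every population-B sample; symmetrically
    for UET-B.
    """
    cols_a, cols_b = _pop_columns(design, tissue)
    va = tissue_matrix.values[cols_a]
    vb = tissue_matrix.values[cols_b]
    present_a = (va > presence_eps).all(axis=1)
    present_b = (vb > presence_eps).all(axis=1)
    absent_a = (va == 0).all(axis=1)
    absent_b = (vb == 0).all(axis=1)
    uet_a = set(tissue_matrix.values.index[present_a & absent_b])
    uet_b = set(tissue_matrix.values.index[present_b & absent_a])
    return uet_a, uet_b


def select_eet(
    tissue_counts: ExpressionMatrix,
    design: SampleDesign,
    population: str,
    tissue: str,
    fdr: float = 0.05,
) -> Set[str]:
    """Step 2: transcripts equally expressed across all individual pairs.

    Runs the EB engine on each of the C(n, 2) individual pairs (one library
    per side, matched tissue) and intersects the EE calls.
    """
    if tissue_counts.n_transcripts == 0:
        return set()
    individuals = design.individuals(population)
    if len(individuals) < 2:
        logger.warning(
            "population %r has a single individual; EET set is the full index",
            population,
        )
        return set(tissue_counts.values.index)
    eet: Optional[Set[str]] = None
    for i in range(len(individuals)):
        for j in range(i + 1, len(individuals)):
            si = design.sample_for(population, individuals[i], tissue)
            sj = design.sample_for(population, individuals[j], tissue)
            fit = fit_eb(
                tissue_counts.values[[si]], tissue_counts.values[[sj]]
            )
            calls = set(call_ee(fit, fdr=fdr))
            eet = calls if eet is None else (eet & calls)
    return eet if eet is not None else set()


def detect_det(
    tissue_counts: ExpressionMatrix,
    design: SampleDesign,
    eet_both: Set[str],
    tissue: Optional[str] = None,
    fdr: float = 0.05,
    min_fc: float = 1.5,
) -> pd.DataFrame:
    """Step 3: differential calls between populations within EET-both."""
    missing = eet_both - set(tissue_counts.values.index)
    if missing:
        raise ValueError(f"eet_both contains unknown transcripts: {sorted(missing)[:3]}")
    if not eet_both:
        return pd.DataFrame(columns=["PPDE", "PPEE", "FC", "direction"])
    cols_a, cols_b = _pop_columns(design, tissue)
    keep = [t for t in tissue_counts.values.index if t in eet_both]
    sub = tissue_counts.values.loc[keep]
    fit = fit_eb(sub[cols_a], sub[cols_b])
    table = call_de(fit, fdr=fdr, min_fc=min_fc)
    pop_a, pop_b = design.populations
    table = table[table["called"]].copy()
    table["direction"] = np.where(table["FC"] >= 1.0, pop_a, pop_b)
    return table.drop(columns=["called"])


@dataclass
class PipelineConfig:
    fdr: float = 0.05
    min_fc: float = 1.5
    presence_eps: float = 0.0
    uet_mode: str = "per_tissue"  # or "global"


def run_pipeline(
    counts: ExpressionMatrix,
    design: SampleDesign,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Execute steps 1-3 for every tissue of the design.

    Presence/absence (step 1) is evaluated on FPKM; the EB engine (steps 2
    and 3) consumes raw counts, which is what the NB model describes.
    After step 1, only transcripts expressed somewhere in both populations
    enter step 2.
    """
    config = config or PipelineConfig()
    pop_a, pop_b = design.populations
    fpkm_matrix = fpkm(counts) if counts.unit == "count" else counts

    global_uet: Optional[Tuple[Set[str], Set[str]]] = None
    if config.uet_mode == "global":
        global_uet = classify_uet(
            fpkm_matrix, design, tissue=None, presence_eps=config.presence_eps
        )
    elif config.uet_mode != "per_tissue":
        raise ValueError(f"unknown uet_mode {config.uet_mode!r}")

    per_tissue: Dict[str, TissueResult] = {}
    for tissue in design.tissues:
        cols_a, cols_b = _pop_columns(design, tissue)
        tissue_fpkm = fpkm_matrix.subset_samples(cols_a + cols_b)
        tissue_counts = counts.subset_samples(cols_a + cols_b)

        if global_uet is not None:
            uet_a, uet_b = global_uet
        else:
            uet_a, uet_b = classify_uet(
                tissue_fpkm, design, tissue=tissue, presence_eps=config.presence_eps
            )

        # transcripts expressed in individuals from both populations
        va, vb = tissue_fpkm.values[cols_a], tissue_fpkm.values[cols_b]
        in_both = (va > config.presence_eps).any(axis=1) & (
            vb > config.presence_eps
        ).any(axis=1)
        step2_ids = tissue_counts.values.index[in_both]
        step2 = tissue_counts.subset_transcripts(step2_ids)

        eet_a = select_eet(step2, design, pop_a, tissue, fdr=config.fdr)
        eet_b = select_eet(step2, design, pop_b, tissue, fdr=config.fdr)
        eet_both = eet_a & eet_b

        det_table = detect_det(
            step2,
            design,
            eet_both,
            tissue=tissue,
            fdr=config.fdr,
            min_fc=config.min_fc,
        )
        res = TissueResult(
            uet_a=uet_a,
            uet_b=uet_b,
            eet_a=eet_a,
            eet_b=eet_b,
            eet_both=eet_both,
            det_table=det_table,
            step_counts={
                "uet_a": len(uet_a),
                "uet_b": len(uet_b),
                "step2_universe": int(in_both.sum()),
                "eet_a": len(eet_a),
                "eet_b": len(eet_b),
                "eet_both": len(eet_both),
                "det": int(det_table.shape[0]),
            },
        )
        res.check_invariants()
        per_tissue[tissue] = res
        logger.info("tissue %s: %s", tissue, res.step_counts)

    return PipelineResult(
        per_tissue=per_tissue,
        populations=(pop_a, pop_b),
        metadata={
            "fdr": config.fdr,
            "min_fc": config.min_fc,
            "presence_eps": config.presence_eps,
            "uet_mode": config.uet_mode,
        },
    )
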