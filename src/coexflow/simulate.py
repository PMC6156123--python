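"""Synthetic two-population field-transcriptomics data with known ground truth.

The generator emulates the sampling design of a comparative field study of a
coastal tree species: two natural populations (equatorial and subtropical),
three individuals per population, five organs (root, stem, leaf, meristem,
flower), one RNA-seq library per individual x organ.  Counts follow a
negative-binomial noise model on top of log-uniform baseline means, with

* UETs (uniquely expressed transcripts): positive in every sample of one
  population, structurally zero in the other;
* DETs: population mean ratio equal to a configured fold change, half
  over-expressed in each population;
* co-expression modules: groups of transcripts sharing a per-sample latent
  log-normal factor, inducing positive pairwise correlation;
* per-tissue mean multipliers (organ identity dominates sample clustering)
  and log-normal library-size factors (depth normalization is non-trivial).

Every planted signal is recorded in a :class:`TruthTable` so downstream
stages can be scored against ground truth.  Companion generators emit
transcript sequences (with planted ORFs, SSR motifs and near-duplicate
pairs) and a GO annotation map with terms enriched in planted modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .abundance import ExpressionMatrix

DEFAULT_TISSUES = ("root", "stem", "leaf", "meristem", "flower")

UET_A = "UET_A"
UET_B = "UET_B"
DET_UP_A = "DET_up_A"
DET_UP_B = "DET_up_B"
BACKGROUND = "EET_background"


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the 2-population x 3-individual x 5-organ design; the
    fold change of planted DETs defaults to 4 and the negative-binomial size
    (dispersion) parameter to 5.
    """

    n_transcripts: int = 2000
    n_individuals_per_pop: int = 3
    tissues: Tuple[str, ...] = DEFAULT_TISSUES
    frac_uet_A: float = 0.05
    frac_uet_B: float = 0.05
    frac_det: float = 0.10
    det_fold_change: float = 4.0
    nb_dispersion: float = 5.0
    baseline_mean_log_range: Tuple[float, float] = (np.log(10.0), np.log(1000.0))
    n_modules: int = 4
    module_size: int = 50
    module_correlation: float = 0.8
    length_range_nt: Tuple[int, int] = (300, 3000)
    n_go_terms: int = 50
    seed: int = 0
    # secondary knobs
    tissue_effect_sd: float = 0.4
    library_size_sd: float = 0.1
    uet_guarantee_presence: bool = True
    p_annot_module: float = 0.8
    p_annot_background: float = 0.05
    orf_fraction: float = 0.5
    ssr_fraction: float = 0.2
    duplicate_pair_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0 or self.n_individuals_per_pop <= 0:
            raise ConfigError("sizes must be positive")
        if not self.tissues:
            raise ConfigError("at least one tissue required")
        for name in ("frac_uet_A", "frac_uet_B", "frac_det"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.frac_uet_A + self.frac_uet_B + self.frac_det > 1.0 + 1e-12:
            raise ConfigError("frac_uet_A + frac_uet_B + frac_det must be <= 1")
        if self.det_fold_change <= 1.0:
            raise ConfigError("det_fold_change must exceed 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not 0.0 <= self.module_correlation < 1.0:
            raise ConfigError("module_correlation must lie in [0, 1)")
        if self.n_modules * self.module_size > self.n_transcripts:
            raise ConfigError("modules do not fit into the transcriptome")


@dataclass
class TruthTable:
    """Ground truth of a synthetic run.

    ``table`` is indexed by transcript id with columns ``class`` (one of
    UET_A / UET_B / DET_up_A / DET_up_B / EET_background), ``module``
    (integer id or -1), ``length`` (nt) and, once sequences have been
    generated, ``has_orf``, ``ssr_motif`` and ``duplicate_of``.
    ``go_enrichment`` maps each planted GO term to the module it is
    enriched in.
    """

    table: pd.DataFrame
    go_enrichment: Dict[str, int] = field(default_factory=dict)

    def transcripts_in_class(self, cls: str) -> Set[str]:
        return set(self.table.index[self.table["class"] == cls])

    def module_members(self, module: int) -> Set[str]:
        return set(self.table.index[self.table["module"] == module])

    @property
    def modules(self) -> List[int]:
        mods = sorted(m for m in self.table["module"].unique() if m >= 0)
        return [int(m) for m in mods]


@dataclass
class SampleDesign:
    """Maps each sample/library to (population, individual, tissue)."""

    table: pd.DataFrame  # index: sample id; columns: population, individual, tissue

    def __post_init__(self) -> None:
        required = {"population", "individual", "tissue"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        pops = sorted(self.table["population"].unique())
        if len(pops) != 2:
            raise ValueError("design must contain exactly two populations")
        key = self.table[["population", "individual", "tissue"]]
        if key.duplicated().any():
            raise ValueError("duplicate (population, individual, tissue) entry")

    @property
    def populations(self) -> Tuple[str, str]:
        pops = sorted(self.table["population"].unique())
        if len(pops) != 2:
            raise ValueError("design must contain exactly two populations")
        return pops[0], pops[1]

    @property
    def tissues(self) -> List[str]:
        seen: List[str] = []
        for t in self.table["tissue"]:
            if t not in seen:
                seen.append(t)
        return seen

    def samples(
        self, population: Optional[str] = None, tissue: Optional[str] = None
    ) -> List[str]:
        mask = pd.Series(True, index=self.table.index)
        if population is not None:
            mask &= self.table["population"] == population
        if tissue is not None:
            mask &= self.table["tissue"] == tissue
        return list(self.table.index[mask])

    def individuals(self, population: str) -> List[str]:
        return sorted(self.table.loc[self.table["population"] == population, "individual"].unique())

    def sample_for(self, population: str, individual: str, tissue: str) -> str:
        mask = (
            (self.table["population"] == population)
            & (self.table["individual"] == individual)
            & (self.table["tissue"] == tissue)
        )
        hits = list(self.table.index[mask])
        if len(hits) != 1:
            raise KeyError(f"no unique sample for {(population, individual, tissue)}")
        return hits[0]


def _transcript_ids(n: int) -> List[str]:
    width = max(5, len(str(n)))
    return [f"t{i:0{width}d}" for i in range(1, n + 1)]


def _build_design(config: SimConfig) -> SampleDesign:
    rows = []
    for pop, tag in (("equatorial", "A"), ("subtropical", "B")):
        for ind in range(1, config.n_individuals_per_pop + 1):
            for tissue in config.tissues:
                sample = f"{tag}{ind}_{tissue}"
                rows.append((sample, pop, f"{tag}{ind}", tissue))
    df = pd.DataFrame(rows, columns=["sample", "population", "individual", "tissue"])
    return SampleDesign(df.set_index("sample"))


def simulate_counts(
    config: SimConfig,
) -> Tuple[ExpressionMatrix, SampleDesign, TruthTable]:
    """Draw a seeded count matrix with planted UET/DET/module structure.

    Returns the integer count matrix (with planted transcript lengths), the
    sample design, and the ground-truth table.  The same config (hence the
    same seed) reproduces the output exactly.
    """
    rng = np.random.default_rng(config.seed)
    ids = _transcript_ids(config.n_transcripts)
    design = _build_design(config)
    samples = list(design.table.index)
    n_samples = len(samples)
    pop_a, pop_b = design.populations
    is_a = (design.table["population"] == pop_a).to_numpy()
    tissue_of = design.table["tissue"].to_numpy()

    g = config.n_transcripts
    n_uet_a = int(round(config.frac_uet_A * g))
    n_uet_b = int(round(config.frac_uet_B * g))
    n_det = int(round(config.frac_det * g))
    perm = rng.permutation(g)
    classes = np.full(g, BACKGROUND, dtype=object)
    classes[perm[:n_uet_a]] = UET_A
    classes[perm[n_uet_a : n_uet_a + n_uet_b]] = UET_B
    det_idx = perm[n_uet_a + n_uet_b : n_uet_a + n_uet_b + n_det]
    classes[det_idx[: n_det // 2]] = DET_UP_A
    classes[det_idx[n_det // 2 :]] = DET_UP_B

    # modules live among the background transcripts
    module = np.full(g, -1, dtype=int)
    bg_idx = np.flatnonzero(classes == BACKGROUND)
    need = config.n_modules * config.module_size
    if need > len(bg_idx):
        raise ConfigError("not enough background transcripts for modules")
    chosen = rng.choice(bg_idx, size=need, replace=False)
    for m in range(config.n_modules):
        module[chosen[m * config.module_size : (m + 1) * config.module_size]] = m

    lo, hi = config.baseline_mean_log_range
    base_mu = np.exp(rng.uniform(lo, hi, size=g))

    mu = np.tile(base_mu[:, None], (1, n_samples)).astype(float)

    # tissue effects: per transcript x tissue log-normal multiplier, mean 1
    if config.tissue_effect_sd > 0:
        sd = config.tissue_effect_sd
        t_eff = rng.lognormal(-0.5 * sd * sd, sd, size=(g, len(config.tissues)))
        t_index = {t: k for k, t in enumerate(config.tissues)}
        cols = np.array([t_index[t] for t in tissue_of])
        mu *= t_eff[:, cols]

    # DET fold change: geometric split so pop-mean ratio equals the setting
    root_fc = np.sqrt(config.det_fold_change)
    up_a = classes == DET_UP_A
    up_b = classes == DET_UP_B
    mu[np.ix_(up_a, is_a)] *= root_fc
    mu[np.ix_(up_a, ~is_a)] /= root_fc
    mu[np.ix_(up_b, is_a)] /= root_fc
    mu[np.ix_(up_b, ~is_a)] *= root_fc

    # module latent factors: shared per-sample log-normal, mean 1
    rho = config.module_correlation
    if rho > 0:
        for m in range(config.n_modules):
            z = rng.standard_normal(n_samples)
            factor = np.exp(rho * z - 0.5 * rho * rho)
            mu[module == m] *= factor[None, :]

    # library size factors
    if config.library_size_sd > 0:
        lib = rng.lognormal(0.0, config.library_size_sd, size=n_samples)
        mu *= lib[None, :]

    # structural zeros for UETs
    mu[np.ix_(classes == UET_A, ~is_a)] = 0.0
    mu[np.ix_(classes == UET_B, is_a)] = 0.0

    r = config.nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(mu > 0, r / (r + mu), 1.0)
    counts = rng.negative_binomial(r, p)
    counts[mu == 0] = 0

    if config.uet_guarantee_presence:
        counts[np.ix_(classes == UET_A, is_a)] = np.maximum(
            counts[np.ix_(classes == UET_A, is_a)], 1
        )
        counts[np.ix_(classes == UET_B, ~is_a)] = np.maximum(
            counts[np.ix_(classes == UET_B, ~is_a)], 1
        )

    l0, l1 = config.length_range_nt
    lengths = np.rint(np.exp(rng.uniform(np.log(l0), np.log(l1), size=g))).astype(int)

    values = pd.DataFrame(counts, index=ids, columns=samples)
    lengths_s = pd.Series(lengths, index=ids, name="length")
    truth = TruthTable(
        pd.DataFrame(
            {"class": classes, "module": module, "length": lengths},
            index=pd.Index(ids, name="transcript"),
        )
    )
    return ExpressionMatrix(values, lengths_s, "count"), design, truth


_STOPS = ("TAA", "TAG", "TGA")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _plant_orf(rng: np.random.Generator, seq: List[str], orf_nt: int, start: int) -> None:
    """Overwrite seq[start:start+orf_nt] with ATG ... stop, no internal stops."""
    codons = ["ATG"]
    n_internal = orf_nt // 3 - 2
    while len(codons) < n_internal + 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    codons.append(_STOPS[rng.integers(0, 3)])
    orf = "".join(codons)
    seq[start : start + orf_nt] = list(orf)


def simulate_transcripts(
    config: SimConfig, truth: TruthTable
) -> List[SeqRecord]:
    """Emit random-composition sequences at the planted lengths.

    A configurable subset carries planted ORFs (ATG...stop, length >= 300 nt
    where the transcript allows), planted SSR motifs ((AG)x8 style perfect
    tandem repeats), and near-duplicate pairs (a mutated copy of another
    transcript at >= 95% identity over >= 90% of the shorter length).  What
    was planted where is recorded in the truth table.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = list(truth.table.index)
    lengths = truth.table["length"].to_numpy()
    n = len(ids)

    has_orf = np.zeros(n, dtype=bool)
    ssr_motif = np.array([""] * n, dtype=object)
    duplicate_of = np.array([""] * n, dtype=object)

    seqs: List[str] = []
    protected: List[List[Tuple[int, int]]] = []  # planted spans, per transcript
    for i in range(n):
        L = int(lengths[i])
        spans: List[Tuple[int, int]] = []
        seq = list(_random_seq(rng, L))
        if rng.random() < config.orf_fraction and L >= 120:
            orf_nt = min(L - L % 3, max(300, 3 * (L // 6)))
            orf_nt = min(orf_nt, L)
            orf_nt -= orf_nt % 3
            if orf_nt >= 120:
                start = int(rng.integers(0, L - orf_nt + 1))
                _plant_orf(rng, seq, orf_nt, start)
                has_orf[i] = True
                spans.append((start, start + orf_nt))
        if rng.random() < config.ssr_fraction and L >= 40:
            motif = ["A", "AG", "ATC", "AATG", "AACGT", "AACGTG"][int(rng.integers(0, 6))]
            reps = {1: 12, 2: 8, 3: 6, 4: 6, 5: 5, 6: 5}[len(motif)]
            run = motif * reps
            if len(run) + 2 < L:
                start = int(rng.integers(1, L - len(run) - 1))
                seq[start : start + len(run)] = list(run)
                # break accidental extension on both flanks
                seq[start - 1] = "C" if seq[start - 1] == run[-1] else seq[start - 1]
                seq[start + len(run)] = (
                    "C" if seq[start + len(run)] == run[0] else seq[start + len(run)]
                )
                ssr_motif[i] = motif
                spans.append((start - 1, start + len(run) + 1))
        seqs.append("".join(seq))
        protected.append(spans)

    n_dup = int(round(config.duplicate_pair_fraction * n / 2))
    if n_dup > 0:
        pool = rng.permutation(n)[: 2 * n_dup]
        for k in range(n_dup):
            src, dst = int(pool[2 * k]), int(pool[2 * k + 1])
            template = seqs[src]
            copy = list(template)
            # mutate outside planted ORF/SSR spans so inherited truth holds
            mutable = np.ones(len(copy), dtype=bool)
            for lo, hi in protected[src]:
                mutable[max(lo, 0) : min(hi, len(copy))] = False
            candidates = np.flatnonzero(mutable)
            n_mut = min(int(0.02 * len(copy)), len(candidates))
            for pos in rng.choice(candidates, size=n_mut, replace=False):
                alt = "ACGT".replace(copy[pos], "")
                copy[pos] = alt[int(rng.integers(0, 3))]
            seqs[dst] = "".join(copy)
            lengths[dst] = len(seqs[dst])
            duplicate_of[dst] = ids[src]
            has_orf[dst] = has_orf[src]
            ssr_motif[dst] = ssr_motif[src]

    truth.table["has_orf"] = has_orf
    truth.table["ssr_motif"] = ssr_motif
    truth.table["duplicate_of"] = duplicate_of
    truth.table["length"] = lengths

    return [
        SeqRecord(Seq(s), id=tid, description="") for tid, s in zip(ids, seqs)
    ]


def simulate_annotation(
    truth: TruthTable, config: SimConfig
) -> Dict[str, Set[str]]:
    """Assign GO terms, enriching one term per planted module.

    The first ``n_modules`` terms are planted: module members receive the
    term with probability ``p_annot_module`` (default 0.8) and all other
    transcripts with probability ``p_annot_background`` (default 0.05).
    Remaining terms annotate every transcript at the background rate.
    Returns transcript id -> set of GO term ids; planted term -> module
    assignments are recorded in ``truth.go_enrichment``.
    """
    rng = np.random.default_rng(config.seed + 2)
    ids = list(truth.table.index)
    if not ids:
        return {}
    terms = [f"GO:{i:07d}" for i in range(1, config.n_go_terms + 1)]
    modules = truth.modules
    truth.go_enrichment = {terms[k]: m for k, m in enumerate(modules[: len(terms)])}

    ann: Dict[str, Set[str]] = {tid: set() for tid in ids}
    module_col = truth.table["module"].to_numpy()
    for k, term in enumerate(terms):
        planted_module = truth.go_enrichment.get(term)
        probs = np.full(len(ids), config.p_annot_background)
        if planted_module is not None:
            probs[module_col == planted_module] = config.p_annot_module
        hits = rng.random(len(ids)) < probs
        for tid in np.array(ids)[hits]:
            ann[tid].add(term)
    return {tid: s for tid, s in ann.items() if s}
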