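"""Codon-adaptation abundance proxies.

Three per-gene scores stand in for directly measured protein abundance:
the classic codon adaptation index (geometric mean of relative-adaptiveness
weights), an optimal-codon deviation score mean (O-E)/E over degeneracy
classes, and a log-odds score contrasting codon frequencies in the top vs
bottom abundance quartiles. The first 20 codons are skipped throughout
(5' ends are AT-enriched and under different selection); the log-odds path
uses a central 10-codon window to focus on elongation-associated bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CodingSequence",
    "OptimalCodonSet",
    "synonymous_blocks",
    "read_cds_fasta",
    "effective_codons",
    "cai_weights_from_counts",
    "load_packaged_cai_weights",
    "cai_score",
    "derive_optimal_codons",
    "deviation_score",
    "codon_log_odds",
    "log_odds_score",
]

_BASES = set("ACGT")


def synonymous_blocks() -> dict:
    """Amino acid -> sorted synonymous codons (standard code; stops under '*').

    Six-fold families (Leu, Ser, Arg) are single blocks of degeneracy 6.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    blocks: dict[str, list] = {}
    for codon, aa in table.forward_table.items():
        blocks.setdefault(aa, []).append(codon)
    blocks["*"] = list(table.stop_codons)
    return {aa: sorted(codons) for aa, codons in blocks.items()}


_BLOCKS = synonymous_blocks()
_CODON_TO_AA = {codon: aa for aa, codons in _BLOCKS.items() for codon in codons}
_STOPS = frozenset(_BLOCKS["*"])
#: codons excluded from CAI scoring: stops and single-codon families (Met, Trp)
_CAI_EXCLUDED = _STOPS | {c for aa, cs in _BLOCKS.items() if len(cs) == 1 for c in cs}
ALL_CODONS = sorted(_CODON_TO_AA)


@dataclass
class CodingSequence:
    """A validated CDS as a codon list (length divisible by 3, ACGT only,
    stop codons only terminal)."""

    gene_id: str
    codons: list

    @classmethod
    def from_sequence(cls, gene_id: str, seq: str) -> "CodingSequence":
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise ValueError(f"{gene_id}: length {len(seq)} not divisible by 3")
        if not set(seq) <= _BASES:
            raise ValueError(f"{gene_id}: non-ACGT characters")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if any(c in _STOPS for c in codons[:-1]):
            raise ValueError(f"{gene_id}: internal stop codon")
        return cls(gene_id, codons)


def read_cds_fasta(path) -> tuple[list, list]:
    """Read and validate CDSs from FASTA; returns (sequences, skip_log).

    The first whitespace token of each header is the gene id. Records that
    fail validation (length, alphabet, internal stop) are skipped and listed
    in the log as (gene_id, reason).
    """
    seqs: list[CodingSequence] = []
    skipped: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seqs.append(CodingSequence.from_sequence(rec.id, str(rec.seq)))
        except ValueError as exc:
            skipped.append((rec.id, str(exc)))
    return seqs, skipped


def effective_codons(seq: CodingSequence, mode: str = "skip20") -> list:
    """The codons of a gene that enter scoring.

    "skip20": codons 21..end, terminal stop excluded. "central10": a
    10-codon window centred at floor(L/2) (L = total codons), shifted right
    so it starts no earlier than codon 21; genes too short for the window
    yield an empty list. "all": every codon except the terminal stop.
    """
    codons = seq.codons
    payload = codons[:-1] if codons and codons[-1] in _STOPS else list(codons)
    if mode == "all":
        return payload
    if mode == "skip20":
        return payload[20:]
    if mode == "central10":
        start = max(len(codons) // 2 - 5, 20)
        if start + 10 > len(payload):
            return []
        return payload[start : start + 10]
    raise ValueError(f"unknown mode {mode!r}")


def cai_weights_from_counts(counts: Mapping[str, float], floor: float = 0.01) -> dict:
    """Relative adaptiveness per codon: count / max count in its block.

    Within each synonymous block the most-used codon gets weight 1; unused
    codons are floored at ``floor`` so geometric means stay defined. Scaling
    all within-block counts by a constant leaves the weights unchanged.
    """
    w: dict[str, float] = {}
    for aa, codons in _BLOCKS.items():
        if aa == "*":
            continue
        cmax = max(counts.get(c, 0.0) for c in codons)
        for c in codons:
            w[c] = max(counts.get(c, 0.0) / cmax, floor) if cmax > 0 else 1.0
    return w


def load_packaged_cai_weights() -> dict:
    """The packaged synthetic example weight table (codon -> w).

    A stand-in reference table for demos and tests, generated from an
    artificial bias pattern — not an empirical organism table.
    """
    text = resources.files("compevol").joinpath("data/cai_weights_synthetic.tsv").read_text()
    w = {}
    for line in text.strip().splitlines()[1:]:
        codon, val = line.split("\t")
        w[codon] = float(val)
    return w


def cai_score(seq: CodingSequence, weights: Mapping[str, float], mode: str = "skip20") -> Optional[float]:
    """Geometric mean of relative-adaptiveness weights over effective codons.

    Stop codons and single-codon families (Met, Trp) carry no usage signal
    and are excluded. Returns None when no scorable codon remains.
    """
    codons = [c for c in effective_codons(seq, mode) if c not in _CAI_EXCLUDED]
    if not codons:
        return None
    logs = [math.log(weights[c]) for c in codons]
    return math.exp(sum(logs) / len(logs))


@dataclass
class OptimalCodonSet:
    """Per-block optimal codons with provenance.

    ``codons`` maps amino acid -> optimal codon for blocks where the
    enrichment and tRNA criteria agree (or enrichment alone when no tRNA
    weights were given); ``excluded`` lists blocks where they disagree.
    """

    codons: dict
    excluded: list
    provenance: str  # "intersection" or "no-tRNA"

    def degeneracy(self, aa: str) -> int:
        return len(_BLOCKS[aa])


def derive_optimal_codons(
    corpus: Sequence[CodingSequence],
    abundances: Mapping[str, float],
    trna_weights: Optional[Mapping[str, float]] = None,
    log_odds: Optional[Mapping[str, float]] = None,
) -> OptimalCodonSet:
    """Optimal codon per synonymous block.

    The enrichment candidate is the block codon with the highest
    high-vs-low-abundance log odds; the tRNA candidate has the highest tRNA
    weight. A block gets an optimal codon only when the two agree; with no
    tRNA weights the enrichment candidate is used alone (flagged "no-tRNA").
    Single-codon blocks and stops never appear.
    """
    n_ab = sum(1 for s in corpus if s.gene_id in abundances)
    if n_ab < 20:
        raise ValueError(f"need at least 20 genes with abundance, got {n_ab}")
    if log_odds is None:
        log_odds = codon_log_odds(corpus, abundances)
    codons: dict[str, str] = {}
    excluded: list[str] = []
    for aa, block in _BLOCKS.items():
        if aa == "*" or len(block) < 2:
            continue
        enrich = max(block, key=lambda c: (log_odds.get(c, -math.inf), c))
        if trna_weights is None:
            codons[aa] = enrich
            continue
        trna = max(block, key=lambda c: (trna_weights.get(c, -math.inf), c))
        if trna == enrich:
            codons[aa] = enrich
        else:
            excluded.append(aa)
    return OptimalCodonSet(codons, excluded, "intersection" if trna_weights is not None else "no-tRNA")


def deviation_score(
    seq: CodingSequence, optimal_set: OptimalCodonSet, mode: str = "skip20"
) -> Optional[float]:
    """Mean (O-E)/E over degeneracy classes, weighted by codon counts.

    Within the effective codons, for each degeneracy class d the codons in
    d-fold blocks with a defined optimal codon contribute O (observed
    optimal-codon count) against E = count/d (uniform-usage expectation).
    Class scores are combined weighted by each class's effective codon
    count. Returns None when no class is represented.
    """
    if not optimal_set.codons:
        raise ValueError("optimal_set is empty")
    eff = effective_codons(seq, mode)
    per_class: dict[int, list[int]] = {}  # d -> [count, optimal count]
    for c in eff:
        aa = _CODON_TO_AA[c]
        if aa not in optimal_set.codons:
            continue
        d = len(_BLOCKS[aa])
        cnt = per_class.setdefault(d, [0, 0])
        cnt[0] += 1
        if c == optimal_set.codons[aa]:
            cnt[1] += 1
    if not per_class:
        return None
    num = 0.0
    wsum = 0
    for d, (count, obs) in per_class.items():
        e = count / d
        num += count * (obs - e) / e
        wsum += count
    return num / wsum


def codon_log_odds(
    corpus: Sequence[CodingSequence],
    abundances: Mapping[str, float],
    mode: str = "central10",
) -> dict:
    """Codon -> ln(high-quartile frequency / low-quartile frequency).

    Genes are ranked by abundance; codon counts over each gene's central-10
    window are tallied separately for the top and bottom quartiles; Haldane
    0.5 pseudo-counts guard zero cells (denominators add 0.5 * 64).
    """
    usable = [s for s in corpus if s.gene_id in abundances and effective_codons(s, mode)]
    if len(usable) < 8:
        raise ValueError(f"need at least 8 genes with abundance and usable windows, got {len(usable)}")
    usable.sort(key=lambda s: (abundances[s.gene_id], s.gene_id))
    k = max(len(usable) // 4, 1)
    lo, hi = usable[:k], usable[-k:]

    def tally(seqs):
        counts = dict.fromkeys(ALL_CODONS, 0)
        total = 0
        for s in seqs:
            for c in effective_codons(s, mode):
                counts[c] += 1
                total += 1
        return counts, total

    c_hi, t_hi = tally(hi)
    c_lo, t_lo = tally(lo)
    if t_hi == 0 or t_lo == 0:
        raise ValueError("a quartile has no usable codon windows")
    denom_hi = t_hi + 0.5 * 64
    denom_lo = t_lo + 0.5 * 64
    return {
        c: math.log((c_hi[c] + 0.5) / denom_hi) - math.log((c_lo[c] + 0.5) / denom_lo)
        for c in ALL_CODONS
    }


def log_odds_score(
    seq: CodingSequence, table: Mapping[str, float], mode: str = "central10"
) -> Optional[float]:
    """Arithmetic mean of per-codon log odds over the gene's window."""
    codons = effective_codons(seq, mode)
    if not codons:
        return None
    return sum(table[c] for c in codons) / len(codons)
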