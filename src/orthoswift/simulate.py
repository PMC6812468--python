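"""Synthetic multi-taxon proteomes with planted orthologous groups.

Each gene family starts from one ancestral protein drawn uniformly over the
20 residues.  Speciation gives every taxon a descendant mutated by
independent per-site substitution; within a taxon a gene may duplicate, and
the duplicate diverges a little further — planting an in-paralog.  Unrelated
decoy sequences can be mixed in.  The generator records full ground truth
(gene → family, planted ortholog and in-paralog pairs) so every pipeline
stage can be checked without external data.

The substitution model is deliberately minimal — uniform replacement by any
of the other 19 residues, no rate heterogeneity and no indels unless the
small-indel mode is switched on — which is enough to exercise seeded search,
banded extension and the orthology rules.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .search import SequenceRecord
from .seeds import STANDARD_AMINO_ACIDS

__all__ = ["SimConfig", "PlantedTruth", "simulate", "shuffle_decoys"]

_RESIDUES = np.frombuffer(STANDARD_AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic proteomes.

    Defaults: 4 taxa, 50 families, ancestral lengths 100-200 residues,
    15% per-site divergence at speciation, 30% duplication probability per
    taxon with 5% extra divergence for the duplicate.
    """

    n_taxa: int = 4
    n_families: int = 50
    ancestral_length_range: Tuple[int, int] = (100, 200)
    speciation_divergence: float = 0.15
    duplication_rate: float = 0.3
    post_duplication_divergence: float = 0.05
    indel_rate: float = 0.0          # per-gene probability of one small indel
    max_indel_length: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_families < 1:
            raise ValueError("need at least one taxon and one family")
        lo, hi = self.ancestral_length_range
        if lo < 30 or hi < lo:
            raise ValueError("ancestral lengths must be >= 30 and ordered")
        for p in (
            self.speciation_divergence,
            self.duplication_rate,
            self.post_duplication_divergence,
            self.indel_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth for a simulated proteome."""

    family_of: Dict[str, str]                 # full gene id -> family id
    ortholog_pairs: List[Tuple[str, str]]     # cross-taxon primary copies
    inparalog_pairs: List[Tuple[str, str]]    # (primary, duplicate) per taxon
    decoys: Set[str] = field(default_factory=set)

    def labels(self, gene_ids: Sequence[str]) -> List[str]:
        """Family label per gene; decoys get unique singleton labels."""
        return [
            self.family_of.get(g, f"decoy:{g}") for g in gene_ids
        ]


def _taxon_names(n: int) -> List[str]:
    if n <= 26:
        return [f"tax{c}" for c in string.ascii_uppercase[:n]]
    return [f"tax{i:03d}" for i in range(n)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution to a uniformly chosen *different* residue."""
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.shape[0]) < rate)[0]
    for i in hit:
        choices = _RESIDUES[_RESIDUES != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def _maybe_indel(
    seq: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.indel_rate <= 0 or rng.random() >= cfg.indel_rate:
        return seq
    length = int(rng.integers(1, cfg.max_indel_length + 1))
    pos = int(rng.integers(1, max(2, seq.shape[0] - length)))
    if rng.random() < 0.5 and seq.shape[0] - length >= 30:
        return np.concatenate([seq[:pos], seq[pos + length:]])
    insert = _RESIDUES[rng.integers(0, len(_RESIDUES), size=length)]
    return np.concatenate([seq[:pos], insert, seq[pos:]])


def simulate(config: SimConfig) -> Tuple[List[SequenceRecord], PlantedTruth]:
    """Generate the proteomes and their ground truth.

    Gene ids encode provenance (``fam012_taxA``, ``fam012_taxA_dup1``) so a
    failing downstream assertion is diagnosable by eye.  A fixed seed makes
    the output byte-identical across runs.
    """
    rng = np.random.default_rng(config.seed)
    taxa = _taxon_names(config.n_taxa)
    records: List[SequenceRecord] = []
    truth = PlantedTruth(family_of={}, ortholog_pairs=[], inparalog_pairs=[])

    lo, hi = config.ancestral_length_range
    for f in range(config.n_families):
        fam_id = f"fam{f:03d}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = _RESIDUES[rng.integers(0, len(_RESIDUES), size=length)]
        primaries: List[str] = []
        for taxon in taxa:
            gene_id = f"{fam_id}_{taxon}"
            full = f"{taxon}|{gene_id}"
            descendant = _mutate(ancestor, config.speciation_divergence, rng)
            descendant = _maybe_indel(descendant, config, rng)
            records.append(
                SequenceRecord(
                    gene_id=gene_id,
                    taxon=taxon,
                    residues=descendant.tobytes().decode(),
                )
            )
            truth.family_of[full] = fam_id
            for other in primaries:
                truth.ortholog_pairs.append((other, full))
            primaries.append(full)

            if rng.random() < config.duplication_rate:
                dup_id = f"{gene_id}_dup1"
                dup_full = f"{taxon}|{dup_id}"
                dup = _mutate(descendant, config.post_duplication_divergence, rng)
                dup = _maybe_indel(dup, config, rng)
                records.append(
                    SequenceRecord(
                        gene_id=dup_id, taxon=taxon,
                        residues=dup.tobytes().decode(),
                    )
                )
                truth.family_of[dup_full] = fam_id
                truth.inparalog_pairs.append((full, dup_full))
    return records, truth


def shuffle_decoys(
    config: SimConfig, n_decoys: int, truth: Optional[PlantedTruth] = None
) -> List[SequenceRecord]:
    """Unrelated uniform-random sequences, assigned round-robin to taxa.

    Decoys belong to no family; when ``truth`` is given they are registered
    in its decoy set (never in a family).
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = np.random.default_rng(config.seed + 10_007)
    taxa = _taxon_names(config.n_taxa)
    lo, hi = config.ancestral_length_range
    out: List[SequenceRecord] = []
    for d in range(n_decoys):
        taxon = taxa[d % len(taxa)]
        length = int(rng.integers(lo, hi + 1))
        seq = _RESIDUES[rng.integers(0, len(_RESIDUES), size=length)]
        gene_id = f"decoy{d:03d}_{taxon}"
        out.append(
            SequenceRecord(gene_id=gene_id, taxon=taxon,
                           residues=seq.tobytes().decode())
        )
        if truth is not None:
            truth.decoys.add(f"{taxon}|{gene_id}")
    return out
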