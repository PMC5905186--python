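"""Parsimony-informative sites and quartet topology support.

For a four-taxon nucleotide alignment, an alignment column is parsimony
informative in the quartet sense when it shows exactly two states, each
carried by exactly two taxa (an xxyy pattern).  Such a column supports
exactly one of the three unrooted quartet topologies (12|34, 13|24, 14|23).
Tabulating support per gene and comparing winning topologies across genes
measures phylogenetic incongruence, the signature of incomplete lineage
sorting or introgression between recently separated populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "PAIRINGS",
    "TopologySupport",
    "load_quartet",
    "informative_sites",
    "topology_support",
    "is_congruent",
]

#: The three unrooted quartets as index pairings: taxa {i, j} vs the rest.
PAIRINGS = ((0, 1), (0, 2), (0, 3))

_VALID = frozenset("ACGT")


def _partition_label(taxa: tuple[str, ...], pair: tuple[int, int]) -> str:
    # canonical form: names sorted within pairs, pairs sorted, so the label
    # is independent of the input order of the four records
    left = sorted(taxa[i] for i in pair)
    right = sorted(taxa[i] for i in range(4) if i not in pair)
    sides = sorted([left, right])
    return f"{sides[0][0]},{sides[0][1]}|{sides[1][0]},{sides[1][1]}"


@dataclass
class TopologySupport:
    """Informative-site support for the three quartet topologies of a gene."""

    gene: str
    taxa: tuple[str, ...]
    counts: dict[str, int]                      # partition label -> count
    sites: list[tuple[int, str]] = field(default_factory=list)  # (1-based pos, label)

    @property
    def n_informative(self) -> int:
        return sum(self.counts.values())

    @property
    def winning_topology(self) -> Optional[str]:
        """Partition label with the maximal count; ``None`` if unresolved.

        Unresolved means no informative site, or a tie at the maximum.
        """
        if self.n_informative == 0:
            return None
        best = max(self.counts.values())
        winners = [t for t, c in self.counts.items() if c == best]
        return winners[0] if len(winners) == 1 else None


def load_quartet(path, gene: Optional[str] = None) -> MultipleSeqAlignment:
    """Read a 4-sequence FASTA alignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 4:
        raise ValueError(f"{path}: expected exactly 4 sequences, got {len(records)}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{path}: sequences have unequal lengths {sorted(lengths)}")
    aln = MultipleSeqAlignment(records)
    aln.annotations = {"gene": gene or Path(str(path)).stem}
    return aln


def _validate(aln: MultipleSeqAlignment) -> list[str]:
    if len(aln) != 4:
        raise ValueError(f"expected exactly 4 sequences, got {len(aln)}")
    seqs = [str(r.seq).upper() for r in aln]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences have unequal lengths")
    return seqs


def informative_sites(aln: MultipleSeqAlignment) -> list[tuple[int, tuple[int, int]]]:
    """Positions (1-based) and pair patterns of xxyy columns.

    A column qualifies iff it carries exactly two nucleotide states, each in
    exactly two taxa.  Columns containing a gap or ambiguity code in any
    taxon are skipped.  The pattern is the index pair grouped with taxon 0.
    """
    seqs = _validate(aln)
    out = []
    for j in range(len(seqs[0])):
        col = [s[j] for s in seqs]
        if any(b not in _VALID for b in col):
            continue
        states = set(col)
        if len(states) != 2:
            continue
        first = col[0]
        partners = [i for i in range(1, 4) if col[i] == first]
        if len(partners) != 1:
            continue                       # 3:1 split — singleton, uninformative
        out.append((j + 1, (0, partners[0])))
    return out


def topology_support(aln: MultipleSeqAlignment, gene: Optional[str] = None
                     ) -> TopologySupport:
    """Tabulate informative-site support for the three quartet topologies.

    Topologies are labelled by taxon-id partitions (e.g. ``"a,b|c,d"``), so
    reports do not depend on input order conventions.
    """
    taxa = tuple(r.id for r in aln)
    labels = {pair: _partition_label(taxa, pair) for pair in PAIRINGS}
    counts = {labels[pair]: 0 for pair in PAIRINGS}
    sites = []
    for pos, pair in informative_sites(aln):
        counts[labels[pair]] += 1
        sites.append((pos, labels[pair]))
    if gene is None:
        gene = (aln.annotations or {}).get("gene", "") if hasattr(aln, "annotations") else ""
    return TopologySupport(gene=gene or "", taxa=taxa, counts=counts, sites=sites)


def is_congruent(a: TopologySupport, b: TopologySupport) -> bool:
    """Two genes are congruent iff both resolve the same winning topology.

    A gene with no informative sites, or a tied maximum, is unresolved and
    congruent with nothing.
    """
    wa, wb = a.winning_topology, b.winning_topology
    return wa is not None and wa == wb
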