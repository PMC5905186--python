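"""Synthetic inputs with known truth for every stage of the pipeline.

Three generators, all deterministic given a seed:

* :func:`make_site_table` — an observed-style SNP site table whose class
  labels are drawn from a specified multinomial (emulating the structure of
  the published classification), with controllable fractions of sites
  violating each retention filter (shallow depth, clustered positions,
  sub-threshold MAF, bad e-value);
* :func:`make_truth_observed` — "observed" summary statistics produced by
  the forward simulator at a known divergence age, for parameter-recovery
  checks of the dating fit;
* :func:`make_quartet` — four-taxon alignments built on a known topology
  with no homoplasy, for the quartet-support module.

The generators abstract pooled sequencing to allele counts: read-level
noise, base-calling error and the pooling protocol itself are not emulated.
Within a class, the minor allele frequency of a polymorphic population is
drawn uniformly from (maf_min, 0.5]; class membership, not the within-class
frequency, drives every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import DemographicParams, WrightFisherSimulator
from .sites import SITE_COLUMNS, SummaryStats

__all__ = ["TableSpec", "make_site_table", "make_truth_observed", "make_quartet"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TableSpec:
    """Recipe for a synthetic SNP site table.

    ``class_probabilities`` is an 8-vector over the joint SNP classes;
    class 8 (divergent polymorphism) must have probability 0 because a
    three-allele site cannot be represented in the biallelic table schema.
    ``n_sites`` maps annotation categories to site counts.  The ``frac_*``
    fields inject disjoint subsets of sites that violate exactly one
    retention rule each.
    """

    # default: the observed synonymous class frequencies (classes 1-7)
    class_probabilities: tuple[float, ...] = tuple(
        c / 4203 for c in (540, 280, 476, 119, 2086, 393, 309)
    ) + (0.0,)
    n_sites: Mapping[str, int] = field(
        default_factory=lambda: {"synonymous": 2000}
    )
    depth_log_mean: float = 6.0      # lognormal depth, roughly mean ~700
    depth_log_sd: float = 0.8
    min_depth: int = 100
    maf_min: float = 0.05
    max_evalue: float = 1e-5
    min_isolation_bp: int = 50
    frac_shallow_depth: float = 0.0
    frac_clustered: float = 0.0
    frac_low_maf: float = 0.0
    frac_bad_evalue: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probabilities, dtype=float)
        if probs.shape != (8,):
            raise ValueError("class_probabilities must have length 8")
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probabilities must be a probability vector")
        if probs[7] > 0:
            raise ValueError(
                "divergent-polymorphism sites (class 8) need a third allele "
                "and cannot be represented in the biallelic table schema"
            )
        if any(n < 0 for n in self.n_sites.values()):
            raise ValueError("n_sites must be non-negative")
        fracs = (self.frac_shallow_depth, self.frac_clustered,
                 self.frac_low_maf, self.frac_bad_evalue)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("filter-failure fractions must be in [0,1] "
                             "and sum to at most 1")


def _draw_maf(rng: np.random.Generator, maf_min: float, size: int) -> np.ndarray:
    # uniform on (maf_min, 0.5]
    return 0.5 - rng.random(size) * (0.5 - maf_min)


def _counts_for(rng, kind: str, depth: int, maf_min: float) -> tuple[int, int]:
    """(ancestral copies, derived copies) for one population.

    ``kind`` is 'anc' (fixed ancestral), 'der' (fixed derived) or 'poly'.
    Polymorphic draws guarantee MAF strictly above threshold at the given
    depth.
    """
    if kind == "anc":
        return depth, 0
    if kind == "der":
        return 0, depth
    maf = float(_draw_maf(rng, maf_min, 1)[0])
    minor = int(round(maf * depth))
    floor_minor = int(np.floor(maf_min * depth)) + 1   # smallest count with MAF > threshold
    minor = min(max(minor, floor_minor), depth - floor_minor)
    if rng.random() < 0.5:
        return depth - minor, minor     # derived is minor
    return minor, depth - minor         # ancestral is minor


# per-class population configurations: (surface, cave)
_CLASS_CONFIG = {
    1: ("anc", "der"), 2: ("der", "anc"),
    3: ("anc", "poly"), 4: ("der", "poly"),
    5: ("poly", "anc"), 6: ("poly", "der"),
    7: ("poly", "poly"),
}


def make_site_table(spec: TableSpec = TableSpec(), seed=None) -> pd.DataFrame:
    """Materialize a site table realizing ``spec``.

    Sites are laid out on contigs of up to five SNPs spaced 200 bp apart
    (comfortably beyond the isolation threshold).  Filter-violating sites
    form disjoint subsets, each failing exactly its intended rule:
    shallow-depth sites have depth below ``min_depth`` in one population,
    clustered sites come in pairs 30 bp apart, low-MAF sites carry all
    their variation below the calling threshold, and bad-e-value sites sit
    on contigs with e-value above ``max_evalue``.  The outgroup always
    carries the ancestral allele.
    """
    rng = np.random.default_rng(seed)
    rows = []
    contig_serial = 0
    for category, n in spec.n_sites.items():
        if n == 0:
            continue
        n_shallow = int(round(spec.frac_shallow_depth * n))
        n_clustered = int(round(spec.frac_clustered * n))
        n_clustered -= n_clustered % 2          # clustered sites come in pairs
        n_low_maf = int(round(spec.frac_low_maf * n))
        n_bad_ev = int(round(spec.frac_bad_evalue * n))
        n_clean = n - n_shallow - n_clustered - n_low_maf - n_bad_ev
        if n_clean < 0:
            raise ValueError("filter-failure fractions exceed the site count")
        classes = 1 + rng.choice(7, size=n, p=np.asarray(
            spec.class_probabilities[:7]) / sum(spec.class_probabilities[:7]))
        class_iter = iter(int(c) for c in classes)

        def emit(contig: str, pos: int, kind: str, evalue: float) -> None:
            cls = next(class_iter)
            anc, der = rng.choice(4, size=2, replace=False)
            anc_b, der_b = _BASES[anc], _BASES[der]
            depth_sf = max(int(rng.lognormal(spec.depth_log_mean,
                                             spec.depth_log_sd)),
                           spec.min_depth)
            depth_cf = max(int(rng.lognormal(spec.depth_log_mean,
                                             spec.depth_log_sd)),
                           spec.min_depth)
            if kind == "shallow":
                depth_sf = int(rng.integers(10, spec.min_depth))
            if kind == "low_maf":
                # all variation sub-threshold: both populations fixed for
                # the ancestral allele, one with a tiny minor count
                minor = max(int(spec.maf_min * depth_sf) - 1, 1)
                sf = (depth_sf - minor, minor)
                cf = (depth_cf, 0)
            else:
                sf_kind, cf_kind = _CLASS_CONFIG[cls]
                sf = _counts_for(rng, sf_kind, depth_sf, spec.maf_min)
                cf = _counts_for(rng, cf_kind, depth_cf, spec.maf_min)
            swap = rng.random() < 0.5         # randomize allele column order
            a1, a2 = (der_b, anc_b) if swap else (anc_b, der_b)
            sf_c = (sf[1], sf[0]) if swap else sf
            cf_c = (cf[1], cf[0]) if swap else cf
            rows.append({
                "contig": contig, "pos": pos,
                "allele1": a1, "allele2": a2,
                "sf_count1": sf_c[0], "sf_count2": sf_c[1],
                "cf_count1": cf_c[0], "cf_count2": cf_c[1],
                "sf_depth": sum(sf), "cf_depth": sum(cf),
                "outgroup": anc_b, "annotation": category,
                "evalue": evalue,
                "true_class": (0 if kind != "clean" else cls),
                "failure": kind,
            })

        def good_evalue() -> float:
            return spec.max_evalue * 10 ** (-rng.uniform(1, 40))

        def new_contig() -> str:
            nonlocal contig_serial
            contig_serial += 1
            return f"ctg{contig_serial:06d}"

        # clean / shallow / low-MAF sites share multi-site contigs with
        # well-separated positions; their rules do not interact
        mixed = (["clean"] * n_clean + ["shallow"] * n_shallow
                 + ["low_maf"] * n_low_maf)
        rng.shuffle(mixed)
        i = 0
        while i < len(mixed):
            per_contig = min(int(rng.integers(1, 6)), len(mixed) - i)
            contig = new_contig()
            ev = good_evalue()
            for j in range(per_contig):
                emit(contig, 101 + 200 * j, mixed[i + j], ev)
            i += per_contig
        # clustered sites: dedicated contigs, one pair 30 bp apart
        for _ in range(n_clustered // 2):
            contig = new_contig()
            ev = good_evalue()
            emit(contig, 101, "clustered", ev)
            emit(contig, 131, "clustered", ev)
        # bad-e-value sites: alone on their (badly annotated) contig
        for _ in range(n_bad_ev):
            emit(new_contig(), 101,
                 "bad_evalue", spec.max_evalue * 10 ** rng.uniform(0, 3))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS + ["true_class", "failure"])
    return df


def make_truth_observed(params: DemographicParams, true_age: int, seed=None):
    """Simulator-generated observed statistics at a known divergence age.

    Runs the forward model to ``true_age`` (which must be a multiple of the
    checkpoint interval) and returns ``(stats, truth)`` where ``stats`` is
    the :class:`~cavedate.sites.SummaryStats` of the final checkpoint and
    ``truth`` records the generating parameters for recovery tests.
    """
    if true_age % params.checkpoint_years:
        raise ValueError("true_age must be a multiple of checkpoint_years")
    run_params = params.with_(max_years=max(true_age, params.checkpoint_years))
    sim = WrightFisherSimulator(run_params, seed=seed)
    traj = sim.run_split()
    row = traj.table[traj.table["year"] == true_age].iloc[0]
    freqs = np.array([row[f"freq_{k}"] for k in range(1, 8)])
    n = int(row["n_classified"])
    counts = np.rint(freqs * n).astype(int)
    stats = SummaryStats.from_counts(counts)
    truth = {"params": params, "true_age": true_age, "seed": seed,
             "n_classified": n, "class_freqs": freqs}
    return stats, truth


def make_quartet(topology: tuple[int, int] | str, n_informative: int,
                 n_uninformative: int, seed=None,
                 taxa: Sequence[str] = ("t1", "t2", "t3", "t4"),
                 gene: str = "gene") -> MultipleSeqAlignment:
    """Four-taxon alignment whose informative sites all support ``topology``.

    ``topology`` is the index pair grouped with taxon 0 — ``(0, 1)``,
    ``(0, 2)`` or ``(0, 3)`` — or a string like ``"12|34"`` in 1-based
    positional notation.  Uninformative columns are constant or singleton
    columns; no column contradicts the requested topology (no homoplasy).
    """
    if isinstance(topology, str):
        left = topology.split("|")[0]
        pair = tuple(sorted(int(c) - 1 for c in left if c.isdigit()))
    else:
        pair = tuple(sorted(topology))
    if 0 not in pair or pair not in ((0, 1), (0, 2), (0, 3)):
        raise ValueError(f"topology must pair taxon 0 with one other taxon, got {topology}")
    if len(taxa) != 4:
        raise ValueError("exactly four taxon names required")
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(n_informative):
        x, y = rng.choice(4, size=2, replace=False)
        col = [_BASES[y]] * 4
        for i in (0, pair[1]):
            col[i] = _BASES[x]
        cols.append(col)
    for _ in range(n_uninformative):
        b = _BASES[rng.integers(4)]
        col = [b] * 4
        if rng.random() < 0.3:                # singleton column
            alt = _BASES[(int(np.where(_BASES == b)[0][0]) + 1 + rng.integers(3)) % 4]
            col[rng.integers(4)] = alt
        cols.append(col)
    order = rng.permutation(len(cols))
    mat = [[cols[j][i] for j in order] for i in range(4)]
    records = [SeqRecord(Seq("".join(mat[i])), id=taxa[i], description="")
               for i in range(4)]
    aln = MultipleSeqAlignment(records)
    aln.annotations = {"gene": gene}
    return aln
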