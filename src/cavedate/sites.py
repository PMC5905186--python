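"""Classification of biallelic SNP sites into joint polymorphism classes.

A site observed in two populations (surface fish ``SF`` and cavefish ``CF``)
and polarized with an outgroup falls into one of eight classes describing the
joint configuration of ancestral and derived alleles:

====== =========================================================
class  configuration
====== =========================================================
1      SF fixed ancestral, CF fixed derived
2      SF fixed derived,  CF fixed ancestral
3      CF polymorphic, SF fixed ancestral
4      CF polymorphic, SF fixed derived
5      SF polymorphic, CF fixed ancestral
6      SF polymorphic, CF fixed derived
7      shared polymorphism (same allele pair segregating in both)
8      divergent polymorphism (both polymorphic, different pairs)
====== =========================================================

"Fixed" means the minor allele frequency does not exceed the calling
threshold ``maf_min`` (pooled sequencing yields noisy frequencies, so a
strictly-zero criterion is not usable).  Class counts per annotation
category (synonymous / non-synonymous / non-coding) and the summary
statistics derived from them are the observable that the forward simulator
(:mod:`cavedate.simulate`) is fitted against.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DISCARDED",
    "CLASS_LABELS",
    "ANNOTATION_CATEGORIES",
    "FilterThresholds",
    "SummaryStats",
    "OBSERVED_CLASS_COUNTS",
    "observed_class_frequencies",
    "polarize",
    "classify_site",
    "apply_filters",
    "classify_table",
    "tally",
    "summarize",
    "SiteClassifier",
    "read_sites_tsv",
    "write_sites_tsv",
    "read_tally_tsv",
    "write_tally_tsv",
    "read_sites_vcf",
]

#: Sentinel class value for sites that cannot be classified.
DISCARDED = 0

CLASS_LABELS = {
    1: "ancestral fixed SF, derived fixed CF",
    2: "ancestral fixed CF, derived fixed SF",
    3: "polymorphism CF, ancestral fixed SF",
    4: "polymorphism CF, derived fixed SF",
    5: "polymorphism SF, ancestral fixed CF",
    6: "polymorphism SF, derived fixed CF",
    7: "shared polymorphism",
    8: "divergent polymorphism",
}

ANNOTATION_CATEGORIES = ("synonymous", "non_coding", "non_synonymous", "unannotated")

_NUCLEOTIDES = frozenset("ACGT")

#: Published per-class site counts for the Astyanax mexicanus Pachon-cave /
#: Texas-surface pooled-embryo transcriptome comparison (Hyphessobrycon
#: anisitsi outgroup), at thresholds depth >= 100, MAF > 5%, e-value < 1e-5,
#: isolation > 50 bp.  Classes 1..8 per category; the non-synonymous class-2
#: count is 211, consistent with the category total (2110) and every derived
#: summary row.
OBSERVED_CLASS_COUNTS: dict[str, tuple[int, ...]] = {
    "synonymous": (540, 280, 476, 119, 2086, 393, 309, 1),
    "non_coding": (157, 111, 146, 57, 601, 87, 80, 0),
    "non_synonymous": (301, 211, 302, 91, 923, 159, 123, 0),
}

# required columns of the site-table TSV, in canonical order
SITE_COLUMNS = [
    "contig", "pos", "allele1", "allele2",
    "sf_count1", "sf_count2", "cf_count1", "cf_count2",
    "sf_depth", "cf_depth", "outgroup", "annotation", "evalue",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Site-retention thresholds.

    ``min_depth`` is inclusive (depth >= 100 retains); the remaining three
    are strict as conventionally quoted: MAF > ``maf_min``, e-value <
    ``max_evalue``, nearest-neighbour distance > ``min_isolation_bp``.
    """

    min_depth: int = 100
    maf_min: float = 0.05
    max_evalue: float = 1e-5
    min_isolation_bp: int = 50

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_isolation_bp < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")


@dataclass(frozen=True)
class SummaryStats:
    """Summary statistics over the seven populated SNP classes.

    ``class_freqs`` are the relative frequencies of classes 1-7 (divergent
    polymorphism, class 8, is excluded from the frequency vector: it is
    essentially absent from data and structurally absent from the
    infinite-sites simulator).  Ratios are stored at full precision; use
    :meth:`rounded` for reporting at two decimals.  Undefined ratios
    (zero denominator) are signalled as ``nan``.
    """

    class_counts: tuple[int, ...]          # classes 1..7
    total: int                             # sum of classes 1..7
    n_class8: int = 0

    @classmethod
    def from_counts(cls, counts: Iterable[float]) -> "SummaryStats":
        c = [int(x) for x in counts]
        if len(c) == 8:
            c, n8 = c[:7], c[7]
        elif len(c) == 7:
            n8 = 0
        else:
            raise ValueError("expected 7 or 8 class counts, got %d" % len(c))
        if any(x < 0 for x in c) or n8 < 0:
            raise ValueError("class counts must be non-negative")
        total = sum(c)
        if total == 0:
            raise ValueError("no classified sites: summary statistics undefined")
        return cls(class_counts=tuple(c), total=total, n_class8=n8)

    @property
    def class_freqs(self) -> np.ndarray:
        return np.asarray(self.class_counts, dtype=float) / self.total

    @property
    def poly_sf(self) -> int:
        """Sites polymorphic in the surface population: classes 5 + 6 + 7."""
        c = self.class_counts
        return c[4] + c[5] + c[6]

    @property
    def poly_cf(self) -> int:
        """Sites polymorphic in the cave population: classes 3 + 4 + 7."""
        c = self.class_counts
        return c[2] + c[3] + c[6]

    @property
    def fixed_derived_sf(self) -> int:
        """Derived alleles fixed in the surface population: classes 2 + 4."""
        c = self.class_counts
        return c[1] + c[3]

    @property
    def fixed_derived_cf(self) -> int:
        """Derived alleles fixed in the cave population: classes 1 + 6."""
        c = self.class_counts
        return c[0] + c[5]

    @property
    def ratio_sf_cf(self) -> float:
        return self.poly_sf / self.poly_cf if self.poly_cf else math.nan

    @property
    def ratio_cf_sf(self) -> float:
        return self.fixed_derived_cf / self.fixed_derived_sf \
            if self.fixed_derived_sf else math.nan

    def rounded(self) -> dict[str, float]:
        """Reporting view with ratios rounded to two decimals."""
        return {
            "poly_sf": self.poly_sf,
            "poly_cf": self.poly_cf,
            "ratio_sf_cf": round(self.ratio_sf_cf, 2),
            "fixed_derived_sf": self.fixed_derived_sf,
            "fixed_derived_cf": self.fixed_derived_cf,
            "ratio_cf_sf": round(self.ratio_cf_sf, 2),
        }

    def to_json(self) -> str:
        d = self.rounded()
        d["class_counts"] = list(self.class_counts)
        d["class_freqs"] = [float(f) for f in self.class_freqs]
        d["total"] = self.total
        d["n_class8"] = self.n_class8
        return json.dumps(d, indent=2)


def observed_class_frequencies(category: str = "synonymous") -> np.ndarray:
    """Relative frequencies of classes 1-7 in the packaged observed dataset."""
    counts = OBSERVED_CLASS_COUNTS[category]
    return SummaryStats.from_counts(counts).class_freqs


# ---------------------------------------------------------------------------
# per-site operations
# ---------------------------------------------------------------------------

def polarize(alleles: Iterable[str], outgroup: str):
    """Infer (ancestral, derived) from the outgroup allele.

    The allele carried by the outgroup is taken as ancestral.  Returns
    ``None`` when polarization is impossible: outgroup sequence missing
    ("unknown"), polymorphic in the outgroup, a third allele ("other"), or a
    nucleotide matching neither site allele.
    """
    a = [str(x).upper() for x in alleles]
    if len(a) != 2 or a[0] == a[1]:
        raise ValueError(f"a SNP site needs two distinct alleles, got {a}")
    if not set(a) <= _NUCLEOTIDES:
        raise ValueError(f"malformed nucleotide codes: {a}")
    og = str(outgroup).upper()
    if og in ("UNKNOWN", "POLYMORPHIC", "OTHER", "N", "", "."):
        return None
    if og not in _NUCLEOTIDES:
        raise ValueError(f"malformed outgroup allele: {outgroup!r}")
    if og == a[0]:
        return a[0], a[1]
    if og == a[1]:
        return a[1], a[0]
    return None


def _population_state(freqs: Mapping[str, float], maf_min: float):
    """Call a population fixed or polymorphic from per-allele frequencies.

    Returns ``("fixed", {major})``, ``("poly", {a, b})`` or ``None`` when the
    configuration is unusable (more than two alleles above threshold).
    """
    total = float(sum(freqs.values()))
    if total <= 0:
        raise ValueError("population has no observed alleles")
    major = max(freqs, key=lambda k: freqs[k])
    maf = 1.0 - freqs[major] / total
    # tolerance so that a minor frequency exactly at the threshold counts
    # as fixed regardless of floating-point rounding of the division
    if maf <= maf_min + 1e-9:
        return "fixed", {major}
    seg = {a for a, f in freqs.items() if f / total > maf_min + 1e-9}
    if len(seg) > 2:
        return None
    if len(seg) < 2:
        # variation spread over several sub-threshold alleles; call fixed
        return "fixed", {major}
    return "poly", seg


def classify_site(
    sf_state: Mapping[str, float],
    cf_state: Mapping[str, float],
    ancestral: str,
    maf_min: float = 0.05,
) -> int:
    """Assign a polarized site to one of the eight classes.

    ``sf_state`` / ``cf_state`` map alleles to frequencies (or counts) in the
    surface and cave population.  Returns the class 1-8, or :data:`DISCARDED`
    when the joint configuration matches none of the eight patterns (both
    populations fixed for the same allele, more than two alleles segregating
    in one population, or configurations not involving the ancestral allele).
    """
    anc = str(ancestral).upper()
    if anc not in _NUCLEOTIDES:
        raise ValueError(f"malformed ancestral allele: {ancestral!r}")
    sf = _population_state({str(k).upper(): v for k, v in sf_state.items()}, maf_min)
    cf = _population_state({str(k).upper(): v for k, v in cf_state.items()}, maf_min)
    if sf is None or cf is None:
        return DISCARDED
    (sf_kind, sf_al), (cf_kind, cf_al) = sf, cf

    if sf_kind == "fixed" and cf_kind == "fixed":
        (a_sf,), (a_cf,) = sf_al, cf_al
        if a_sf == a_cf:
            return DISCARDED          # monomorphic identical: not a SNP
        if a_sf == anc:
            return 1
        if a_cf == anc:
            return 2
        return DISCARDED              # two derived alleles fixed: unclassifiable

    if sf_kind == "fixed":            # CF polymorphic
        (a_sf,) = sf_al
        if anc not in cf_al:
            return DISCARDED
        if a_sf == anc:
            return 3
        if a_sf in cf_al:
            return 4
        return DISCARDED

    if cf_kind == "fixed":            # SF polymorphic
        (a_cf,) = cf_al
        if anc not in sf_al:
            return DISCARDED
        if a_cf == anc:
            return 5
        if a_cf in sf_al:
            return 6
        return DISCARDED

    # both polymorphic
    if sf_al == cf_al:
        return 7 if anc in sf_al else DISCARDED
    if anc in sf_al and anc in cf_al:
        return 8
    return DISCARDED


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame) -> None:
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table is missing columns: {missing}")


def _pop_maf(df: pd.DataFrame, pop: str) -> pd.Series:
    c1 = df[f"{pop}_count1"].astype(float)
    c2 = df[f"{pop}_count2"].astype(float)
    tot = c1 + c2
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(c1, c2) / tot
    return pd.Series(np.where(tot > 0, maf, 0.0), index=df.index)


def apply_filters(df: pd.DataFrame, thr: FilterThresholds = FilterThresholds()):
    """Apply the four retention rules; return (retained, discard counts).

    Rules are applied in a fixed order and each discarded site is attributed
    to the first rule it fails:

    1. ``depth``   — read depth >= ``min_depth`` in both populations;
    2. ``evalue``  — contig annotation e-value < ``max_evalue``;
    3. ``spacing`` — no other surviving SNP within ``min_isolation_bp`` on
       either side on the same contig (both members of a close pair drop);
    4. ``maf``     — after calling each population fixed/polymorphic at
       ``maf_min``, the site must remain a SNP: sites whose populations are
       both fixed on the same major allele (all variation sub-threshold)
       are discarded.

    The neighbour criterion is evaluated among depth/e-value survivors, so
    re-applying the filters to a retained table changes nothing.
    """
    _check_columns(df)
    discards = {"depth": 0, "evalue": 0, "spacing": 0, "maf": 0}

    ok_depth = (df["sf_depth"] >= thr.min_depth) & (df["cf_depth"] >= thr.min_depth)
    discards["depth"] = int((~ok_depth).sum())
    df1 = df[ok_depth]

    ok_ev = df1["evalue"] < thr.max_evalue
    discards["evalue"] = int((~ok_ev).sum())
    df2 = df1[ok_ev]

    # spacing among survivors, per contig
    keep = pd.Series(True, index=df2.index)
    for _, grp in df2.groupby("contig", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        sp = pos[order]
        bad = np.zeros(len(sp), dtype=bool)
        if len(sp) > 1:
            gap = np.diff(sp)
            close = gap <= thr.min_isolation_bp
            bad[:-1] |= close
            bad[1:] |= close
        keep.loc[grp.index[order[bad]]] = False
    discards["spacing"] = int((~keep).sum())
    df3 = df2[keep]

    maf_sf = _pop_maf(df3, "sf")
    maf_cf = _pop_maf(df3, "cf")
    sf_major = np.where(df3["sf_count1"] >= df3["sf_count2"],
                        df3["allele1"], df3["allele2"])
    cf_major = np.where(df3["cf_count1"] >= df3["cf_count2"],
                        df3["allele1"], df3["allele2"])
    both_fixed = (maf_sf <= thr.maf_min + 1e-9) & (maf_cf <= thr.maf_min + 1e-9)
    no_snp = both_fixed & (sf_major == cf_major)
    discards["maf"] = int(no_snp.sum())
    retained = df3[~no_snp.to_numpy()].copy()
    return retained, discards


def classify_table(
    df: pd.DataFrame,
    thr: FilterThresholds = FilterThresholds(),
):
    """Full observed-site pipeline: filter, polarize, classify.

    Returns ``(classified, discards)`` where ``classified`` is the retained
    table with added columns ``ancestral``, ``derived`` and ``site_class``
    (1-8), and ``discards`` counts removals per rule, including
    ``polarization`` (outgroup unusable) and ``unclassified`` (no class
    pattern matched).
    """
    retained, discards = apply_filters(df, thr)
    anc_col, der_col, cls_col = [], [], []
    mask = np.zeros(len(retained), dtype=bool)
    n_polar = 0
    n_unclass = 0
    for idx, row in enumerate(retained.itertuples(index=False)):
        pol = polarize((row.allele1, row.allele2), row.outgroup)
        if pol is None:
            n_polar += 1
            continue
        anc, der = pol
        sf = {row.allele1: row.sf_count1, row.allele2: row.sf_count2}
        cf = {row.allele1: row.cf_count1, row.allele2: row.cf_count2}
        k = classify_site(sf, cf, anc, thr.maf_min)
        if k == DISCARDED:
            n_unclass += 1
            continue
        anc_col.append(anc)
        der_col.append(der)
        cls_col.append(k)
        mask[idx] = True
    out = retained[mask].copy()
    out["ancestral"] = anc_col
    out["derived"] = der_col
    out["site_class"] = cls_col
    discards = dict(discards)
    discards["polarization"] = n_polar
    discards["unclassified"] = n_unclass
    return out, discards


def tally(classified: pd.DataFrame) -> pd.DataFrame:
    """Count classified sites per annotation category and class.

    Returns a DataFrame indexed by annotation category with columns
    ``class_1`` .. ``class_8`` and ``total``.
    """
    if "site_class" not in classified.columns:
        raise ValueError("table has no 'site_class' column; run classify_table first")
    cats = [c for c in ANNOTATION_CATEGORIES if c in set(classified["annotation"])]
    rows = {}
    for cat in cats:
        sub = classified[classified["annotation"] == cat]
        counts = np.bincount(sub["site_class"].to_numpy(), minlength=9)[1:9]
        rows[cat] = counts
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"class_{k}" for k in range(1, 9)]
    )
    out.index.name = "annotation"
    out["total"] = out.sum(axis=1)
    return out


def summarize(tally_df: pd.DataFrame, category: str) -> SummaryStats:
    """Summary statistics for one annotation category of a class tally."""
    if category not in tally_df.index:
        raise KeyError(f"category {category!r} not present in tally")
    counts = [int(tally_df.loc[category, f"class_{k}"]) for k in range(1, 9)]
    return SummaryStats.from_counts(counts)


class SiteClassifier(TransformerMixin, BaseEstimator):
    """Filter and classify an observed SNP site table.

    A scikit-learn style transformer over a site-table DataFrame.  ``fit``
    runs the pipeline and stores the per-rule discard counts and the class
    tally; ``transform`` returns the classified table (retained sites with
    ``ancestral``, ``derived`` and ``site_class`` columns).

    Parameters mirror :class:`FilterThresholds`.

    Attributes
    ----------
    discard_counts_ : dict
        Sites removed per rule (depth, evalue, spacing, maf, polarization,
        unclassified).
    tally_ : pandas.DataFrame
        Class counts per annotation category.
    n_retained_ : int
        Number of classified sites.
    """

    def __init__(self, min_depth: int = 100, maf_min: float = 0.05,
                 max_evalue: float = 1e-5, min_isolation_bp: int = 50):
        self.min_depth = min_depth
        self.maf_min = maf_min
        self.max_evalue = max_evalue
        self.min_isolation_bp = min_isolation_bp

    def _thresholds(self) -> FilterThresholds:
        return FilterThresholds(self.min_depth, self.maf_min,
                                self.max_evalue, self.min_isolation_bp)

    def fit(self, X: pd.DataFrame, y=None):
        classified, discards = classify_table(X, self._thresholds())
        self.discard_counts_ = discards
        self.tally_ = tally(classified)
        self.n_retained_ = len(classified)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        classified, _ = classify_table(X, self._thresholds())
        return classified

    def summary(self, category: str) -> SummaryStats:
        return summarize(self.tally_, category)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sites_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "outgroup": str,
                                            "annotation": str})
    _check_columns(df)
    for col in ("pos", "sf_count1", "sf_count2", "cf_count1", "cf_count2",
                "sf_depth", "cf_depth"):
        df[col] = df[col].astype(int)
    df["evalue"] = df["evalue"].astype(float)
    if (df["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    return df


def write_sites_tsv(df: pd.DataFrame, path) -> None:
    _check_columns(df)
    df.to_csv(path, sep="\t", index=False, columns=SITE_COLUMNS)


def write_tally_tsv(tally_df: pd.DataFrame, path) -> None:
    """Write a class tally with per-category counts and percentages."""
    out = tally_df.copy()
    for cat in out.index:
        tot = out.loc[cat, "total"]
        for k in range(1, 9):
            out.loc[cat, f"pct_{k}"] = (
                round(100.0 * out.loc[cat, f"class_{k}"] / tot, 1) if tot else math.nan
            )
    out.to_csv(path, sep="\t")


def read_tally_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="annotation")
    cols = [f"class_{k}" for k in range(1, 9)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"tally file missing columns: {missing}")
    return df[cols + (["total"] if "total" in df.columns else [])]


def read_sites_vcf(path, sf_sample: str, cf_sample: str, outgroup_tsv,
                   annotation_info: str = "ANN") -> pd.DataFrame:
    """Build a site table from a VCF plus an outgroup-allele sidecar TSV.

    Allele counts are taken from the per-sample ``AD`` field of the two pool
    columns; the sidecar TSV needs columns ``contig``, ``pos``, ``outgroup``
    (and optionally ``annotation``, ``evalue``).  Multi-allelic records are
    skipped.  Requires :mod:`cyvcf2`.
    """
    from cyvcf2 import VCF  # optional dependency

    side = pd.read_csv(outgroup_tsv, sep="\t", dtype={"contig": str})
    side_key = {(r.contig, int(r.pos)): r for r in side.itertuples(index=False)}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        i_sf, i_cf = samples.index(sf_sample), samples.index(cf_sample)
    except ValueError as e:
        raise ValueError(f"sample not found in VCF: {e}") from None
    rows = []
    for var in vcf:
        if len(var.ALT) != 1 or var.REF is None:
            continue
        key = (var.CHROM, var.POS)
        meta = side_key.get(key)
        ad = var.format("AD")
        if ad is None:
            continue
        sf_ad, cf_ad = ad[i_sf], ad[i_cf]
        rows.append({
            "contig": var.CHROM, "pos": var.POS,
            "allele1": var.REF.upper(), "allele2": var.ALT[0].upper(),
            "sf_count1": int(sf_ad[0]), "sf_count2": int(sf_ad[1]),
            "cf_count1": int(cf_ad[0]), "cf_count2": int(cf_ad[1]),
            "sf_depth": int(sf_ad[0]) + int(sf_ad[1]),
            "cf_depth": int(cf_ad[0]) + int(cf_ad[1]),
            "outgroup": getattr(meta, "outgroup", "unknown") if meta is not None else "unknown",
            "annotation": getattr(meta, "annotation", "unannotated") if meta is not None else "unannotated",
            "evalue": float(getattr(meta, "evalue", 0.0)) if meta is not None else 0.0,
        })
    return pd.DataFrame(rows, columns=SITE_COLUMNS)
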