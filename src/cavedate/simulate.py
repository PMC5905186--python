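"""Forward-in-time neutral SNP simulation for a surface/cave population pair.

The model is an isolation-with-migration scenario on a one-year clock:

* an ancestral diploid Wright-Fisher population of size ``n_anc`` is brought
  to mutation/drift equilibrium under an infinite-sites mutation input of
  ``2*N*u`` new loci per generation, each starting at frequency ``1/(2N)``;
* at year 0 it splits into a surface population (size ``n_sf``, generation
  time ``g_sf`` years) and a cave population (size ``n_cf``, generation time
  ``g_cf`` years), both inheriting the ancestral frequency vector;
* each year a migration pulse from surface to cave occurs with probability
  ``mig_prob_per_year``; a pulse replaces a fraction ``mig_frac`` of the cave
  gene pool by surface gene pool (cave-to-surface migration is neglected);
* every ``checkpoint_years`` years, ``lab_n_fish`` fish are sampled from each
  wild population and propagated ``lab_gens`` generations at effective size
  ``lab_ne`` with no mutation, emulating the establishment of laboratory
  stocks; the lab samples are classified into the seven joint SNP classes
  of :mod:`cavedate.sites` and summary statistics recorded.

All loci are unlinked and neutral; drift is a binomial resampling of ``2N``
allele copies per generation.  Every stochastic step draws from a single
seeded :class:`numpy.random.Generator`, so a run is reproducible bit-for-bit
given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .sites import SummaryStats

__all__ = [
    "DemographicParams",
    "Trajectory",
    "WrightFisherSimulator",
    "expected_fixation_time",
]


@dataclass(frozen=True)
class DemographicParams:
    """All knobs of the two-population forward simulation.

    Defaults are the configuration that fits the Astyanax surface/cave data:
    ancestral and surface size 10,000, cave size 1250, generation times 2
    (surface) and 5 (cave) years, per-haploid-genome mutation probability
    ``u`` = 0.02 per generation, one surface-to-cave migration pulse every
    ~1000 years on average, each replacing 1% of the cave gene pool, and a
    laboratory observation step of 10 fish drifting 10 generations at
    effective size 10.
    """

    n_anc: int = 10_000
    n_sf: int = 10_000
    n_cf: int = 1250
    g_sf: int = 2                 # years per surface generation
    g_cf: int = 5                 # years per cave generation
    u: float = 2e-2               # new-locus probability per haploid genome per generation
    mig_prob_per_year: float = 1e-3
    mig_frac: float = 0.01
    lab_n_fish: int = 10
    lab_ne: int = 10
    lab_gens: int = 10
    checkpoint_years: int = 100
    max_years: int = 40_000
    maf_min: float = 0.05         # polymorphism-calling threshold in lab samples
    burn_in_gens: Optional[int] = None   # default 10 * n_anc

    def __post_init__(self) -> None:
        if min(self.n_anc, self.n_sf, self.n_cf, self.lab_n_fish, self.lab_ne) < 1:
            raise ValueError("population sizes must be >= 1")
        if self.g_sf < 1 or self.g_cf < 1:
            raise ValueError("generation times must be >= 1 year")
        for p in (self.mig_prob_per_year, self.mig_frac, self.maf_min):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if self.u < 0:
            raise ValueError("mutation rate must be non-negative")
        if self.checkpoint_years % self.g_sf or self.checkpoint_years % self.g_cf:
            raise ValueError(
                "checkpoint_years must be a multiple of both generation times"
            )
        if self.lab_gens < 0:
            raise ValueError("lab_gens must be >= 0")

    def mutation_input(self, n: int) -> tuple[float, float]:
        """Expected new loci per generation and their initial frequency.

        In a diploid population of size ``n`` the infinite-sites input is
        ``2*n*u`` new segregating loci per generation, each beginning as a
        single copy at frequency ``1/(2n)``.
        """
        return 2.0 * n * self.u, 1.0 / (2.0 * n)

    @property
    def effective_burn_in_gens(self) -> int:
        return 10 * self.n_anc if self.burn_in_gens is None else self.burn_in_gens

    def with_(self, **kw) -> "DemographicParams":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Per-checkpoint summary statistics of one simulation run."""

    params: DemographicParams
    table: pd.DataFrame            # one row per checkpoint
    shared_substitutions: int      # loci pruned after fixing in both populations

    @property
    def ages(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    @property
    def class_freq_matrix(self) -> np.ndarray:
        cols = [f"freq_{k}" for k in range(1, 8)]
        return self.table[cols].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def expected_fixation_time(p: float, n: int) -> float:
    """Mean generations to fixation of a neutral allele, given it fixes.

    Diffusion-approximation result for an allele at frequency ``p`` in a
    diploid Wright-Fisher population of size ``n``::

        t1(p) = -4 N ((1 - p) / p) ln(1 - p)

    As ``p -> 1/(2N)`` this approaches the classical 4N generations for a
    new mutation destined to fix; as ``p -> 1`` it vanishes.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("initial frequency must lie strictly in (0, 1)")
    if n < 1:
        raise ValueError("population size must be >= 1")
    return -4.0 * n * ((1.0 - p) / p) * math.log1p(-p)


# classification lookup: state codes 0 = fixed ancestral, 1 = polymorphic,
# 2 = fixed derived; LUT[3 * sf_state + cf_state] -> class (0 = excluded)
_CLASS_LUT = np.array([
    0,  # sf anc, cf anc : monomorphic identical
    3,  # sf anc, cf poly
    1,  # sf anc, cf der
    5,  # sf poly, cf anc
    7,  # sf poly, cf poly
    6,  # sf poly, cf der
    2,  # sf der, cf anc
    4,  # sf der, cf poly
    0,  # sf der, cf der : monomorphic identical
], dtype=np.int64)


class WrightFisherSimulator:
    """Two-population forward simulator over independent biallelic loci.

    Frequencies of the derived (mutant) allele are tracked in aligned vectors
    ``freq_sf`` / ``freq_cf``; a locus leaves the system only when its allele
    is absent from both populations (lost) or fixed in both (a shared
    substitution, counted separately).

    Parameters
    ----------
    params :
        Demographic configuration.
    seed :
        Seed (int or :class:`numpy.random.SeedSequence` or Generator) for the
        single random generator driving every stochastic step.
    """

    def __init__(self, params: DemographicParams = DemographicParams(), seed=None):
        self.params = params
        self.rng = np.random.default_rng(seed)

    # -- elementary steps ---------------------------------------------------

    def _drift(self, freqs: np.ndarray, n: int) -> np.ndarray:
        return self.rng.binomial(2 * n, freqs).astype(float) / (2 * n)

    def step_generation(self, freqs: np.ndarray, n: int, u: Optional[float] = None
                        ) -> np.ndarray:
        """One Wright-Fisher generation: binomial drift plus mutation input.

        Existing loci are resampled as Binomial(2n, p)/2n; a Poisson(2nu)
        number of new loci is appended at frequency 1/(2n).
        """
        u = self.params.u if u is None else u
        out = self._drift(np.asarray(freqs, dtype=float), n)
        if u > 0:
            k = self.rng.poisson(2 * n * u)
            if k:
                out = np.concatenate([out, np.full(k, 1.0 / (2 * n))])
        return out

    @staticmethod
    def migrate(freq_cf: np.ndarray, freq_sf: np.ndarray, mig_frac: float
                ) -> np.ndarray:
        """Deterministic admixture of surface gene pool into the cave.

        The pulse replaces ``mig_frac`` of the cave gene pool; stochasticity
        enters through drift at the next cave generation.  Surface
        frequencies are unaffected (cave-to-surface migration neglected).
        """
        if not 0.0 <= mig_frac <= 1.0:
            raise ValueError("mig_frac must lie in [0, 1]")
        return (1.0 - mig_frac) * np.asarray(freq_cf) \
            + mig_frac * np.asarray(freq_sf)

    def lab_sample(self, freqs: np.ndarray) -> np.ndarray:
        """Virtual lab stock: finite fish sample plus lab drift, no mutation.

        Draws ``2 * lab_n_fish`` allele copies from the wild frequencies,
        then applies ``lab_gens`` Wright-Fisher generations at effective size
        ``lab_ne``.  Returns lab derived-allele frequencies; the wild
        populations are unchanged.
        """
        p = self.params
        lab = self.rng.binomial(2 * p.lab_n_fish, freqs).astype(float) \
            / (2 * p.lab_n_fish)
        for _ in range(p.lab_gens):
            lab = self._drift(lab, p.lab_ne)
        return lab

    def classify_simulated(self, lab_sf: np.ndarray, lab_cf: np.ndarray,
                           maf_min: Optional[float] = None):
        """Classify aligned lab frequency vectors into classes 1-7.

        The derived allele is known by construction (the tracked mutant), so
        polarization is implicit.  A population is called fixed when its
        minor allele frequency is <= ``maf_min`` and polymorphic otherwise;
        loci monomorphic-identical in both lab samples are excluded.  Under
        the infinite-sites model each locus carries exactly two alleles, so
        the divergent-polymorphism class (8) cannot occur.

        Returns ``(classes, stats)``: the per-locus class vector (0 for
        excluded loci) and a :class:`~cavedate.sites.SummaryStats`.
        """
        maf = self.params.maf_min if maf_min is None else maf_min
        lab_sf = np.asarray(lab_sf, dtype=float)
        lab_cf = np.asarray(lab_cf, dtype=float)
        if lab_sf.shape != lab_cf.shape:
            raise ValueError("lab frequency vectors must be aligned")

        # tolerance keeps the fixed/polymorphic call symmetric: 1 - 19/20
        # rounds a hair above 1/20 in floating point, and the boundary
        # (minor frequency exactly equal to maf_min) must count as fixed
        thr = maf + 1e-9

        def state(v: np.ndarray) -> np.ndarray:
            minor = np.minimum(v, 1.0 - v)
            s = np.ones(v.shape, dtype=np.int64)       # polymorphic
            s[minor <= thr] = 0
            s[(minor <= thr) & (v > 0.5)] = 2          # fixed derived
            return s

        classes = _CLASS_LUT[3 * state(lab_sf) + state(lab_cf)]
        counts = np.bincount(classes, minlength=8)[1:8]
        stats = SummaryStats.from_counts(counts) if counts.sum() else None
        return classes, stats

    # -- exact observation-layer expectation --------------------------------

    def _lab_state_operator(self) -> np.ndarray:
        """Map an initial lab sample count to final lab-state probabilities.

        Returns a ``(2*lab_n_fish + 1, 3)`` matrix whose row ``k`` is the
        probability that a locus sampled at ``k`` derived copies ends the
        lab phase fixed-ancestral, polymorphic, or fixed-derived.  The lab
        phase is ``lab_gens`` Wright-Fisher generations at ``2*lab_ne``
        copies; states with minor-allele frequency <= ``maf_min`` count as
        fixed, exactly as in :meth:`classify_simulated`.
        """
        from scipy.stats import binom as _binom

        p = self.params
        nf2 = 2 * p.lab_n_fish
        ne2 = 2 * p.lab_ne
        if p.lab_gens == 0:
            dist = np.eye(nf2 + 1)
            grid = nf2
        else:
            j = np.arange(ne2 + 1)
            # one generation from the sample grid onto the lab-Ne grid
            step0 = _binom.pmf(j[None, :], ne2, (np.arange(nf2 + 1) / nf2)[:, None])
            drift = _binom.pmf(j[None, :], ne2, (j / ne2)[:, None])
            dist = step0 @ np.linalg.matrix_power(drift, p.lab_gens - 1)
            grid = ne2
        k = np.arange(grid + 1)
        minor = np.minimum(k, grid - k) / grid
        state = np.ones(grid + 1, dtype=int)
        state[minor <= p.maf_min] = 0
        state[(minor <= p.maf_min) & (k > grid / 2)] = 2
        agg = np.zeros((grid + 1, 3))
        agg[np.arange(grid + 1), state] = 1.0
        return dist @ agg

    def expected_lab_class_counts(self, freq_sf: np.ndarray,
                                  freq_cf: np.ndarray) -> np.ndarray:
        """Expected class counts (classes 1..7) over the lab observation.

        Integrates out the lab sampling and lab drift exactly, per locus:
        the initial sample is Binomial(2*lab_n_fish, p_wild), propagated
        through the lab transition matrix; surface and cave samples are
        independent given the wild frequencies.  Returns float expected
        counts whose total excludes loci monomorphic-identical in both lab
        samples.  This is the noise-free counterpart of
        :meth:`lab_sample` + :meth:`classify_simulated`.
        """
        from scipy.stats import binom as _binom

        if not hasattr(self, "_lab_op_"):
            self._lab_op_ = self._lab_state_operator()
        op = self._lab_op_
        nf2 = 2 * self.params.lab_n_fish
        k = np.arange(nf2 + 1)

        def state_probs(freqs: np.ndarray) -> np.ndarray:
            pmf = _binom.pmf(k[None, :], nf2, np.asarray(freqs)[:, None])
            return pmf @ op                     # (n_loci, 3)

        sf = state_probs(freq_sf)
        cf = state_probs(freq_cf)
        a_sf, p_sf, d_sf = sf[:, 0], sf[:, 1], sf[:, 2]
        a_cf, p_cf, d_cf = cf[:, 0], cf[:, 1], cf[:, 2]
        return np.array([
            np.sum(a_sf * d_cf),    # 1: SF anc, CF der
            np.sum(d_sf * a_cf),    # 2
            np.sum(a_sf * p_cf),    # 3
            np.sum(d_sf * p_cf),    # 4
            np.sum(p_sf * a_cf),    # 5
            np.sum(p_sf * d_cf),    # 6
            np.sum(p_sf * p_cf),    # 7
        ])

    # -- phases -------------------------------------------------------------

    def burn_in(self, record_history: bool = False) -> np.ndarray:
        """Evolve the ancestral population to mutation/drift equilibrium.

        Runs ``effective_burn_in_gens`` Wright-Fisher generations (default
        ``10 * n_anc``, several multiples of the 2N-generation relaxation
        time) with mutation input, pruning lost and fixed loci.  The
        segregating-locus count is tracked; a linear trend over the last
        quarter of the burn-in that exceeds 5% of the mean triggers a
        warning in ``burn_in_stationary_``.

        Returns the equilibrium derived-allele frequency vector.
        """
        p = self.params
        n = p.n_anc
        gens = p.effective_burn_in_gens
        freqs = np.empty(0, dtype=float)
        history = np.empty(gens, dtype=np.int64) if record_history else None
        tail = max(gens // 4, 1)
        tail_counts = np.empty(tail, dtype=np.int64)
        for g in range(gens):
            freqs = self.step_generation(freqs, n)
            freqs = freqs[(freqs > 0.0) & (freqs < 1.0)]
            if record_history:
                history[g] = freqs.size
            if g >= gens - tail:
                tail_counts[g - (gens - tail)] = freqs.size
        if record_history:
            self.burn_in_history_ = history
        # stationarity check: compare mean of the two halves of the tail
        half = tail // 2
        if half > 0:
            a, b = tail_counts[:half].mean(), tail_counts[half:].mean()
            mean = tail_counts.mean()
            self.burn_in_stationary_ = bool(
                mean == 0 or abs(b - a) <= 0.05 * mean
            )
        else:
            self.burn_in_stationary_ = True
        return freqs

    def run_split(self, observed: Optional[np.ndarray] = None,
                  ancestral_freqs: Optional[np.ndarray] = None,
                  lab_stats: str = "sample") -> Trajectory:
        """Simulate the split and record summary statistics per checkpoint.

        Both daughter populations inherit the ancestral frequency vector at
        year 0 and change instantaneously to their own sizes at their first
        reproduction.  Within a year the order of events is: migration pulse
        (Bernoulli), surface reproduction (years divisible by ``g_sf``), cave
        reproduction (years divisible by ``g_cf``), pruning, checkpoint.
        Checkpoints (lab sampling + classification) occur at years
        0, ``checkpoint_years``, 2*``checkpoint_years``, ...

        Parameters
        ----------
        observed :
            Optional 7-vector of observed class frequencies; when given,
            each checkpoint row carries a goodness-of-fit score against it.
        ancestral_freqs :
            Re-use a previously computed equilibrium vector instead of
            running :meth:`burn_in`.
        lab_stats :
            ``"sample"`` (default) draws one virtual lab sample per
            checkpoint, reproducing the noisy observation process;
            ``"expected"`` records the exact expectation of the class
            counts over the lab sampling and lab drift instead
            (:meth:`expected_lab_class_counts`), leaving only the wild
            drift process stochastic.
        """
        if lab_stats not in ("sample", "expected"):
            raise ValueError("lab_stats must be 'sample' or 'expected'")
        p = self.params
        if p.max_years < p.checkpoint_years:
            raise ValueError("simulation horizon shorter than one checkpoint")
        if observed is not None:
            observed = np.asarray(observed, dtype=float)
            if observed.shape != (7,):
                raise ValueError("observed must be a 7-vector of class frequencies")
        if ancestral_freqs is None:
            ancestral_freqs = self.burn_in()
        freq_sf = np.asarray(ancestral_freqs, dtype=float).copy()
        freq_cf = freq_sf.copy()
        shared_subs = 0
        rows = []

        def checkpoint(year: int) -> None:
            if lab_stats == "expected":
                counts = self.expected_lab_class_counts(freq_sf, freq_cf)
            else:
                lab_sf = self.lab_sample(freq_sf)
                lab_cf = self.lab_sample(freq_cf)
                classes = self.classify_simulated(lab_sf, lab_cf)[0]
                counts = np.bincount(classes, minlength=8)[1:8].astype(float)
            total = counts.sum()
            row = {"year": year, "n_loci": freq_sf.size,
                   "shared_substitutions": shared_subs}
            if total == 0:
                row.update({f"freq_{k}": np.nan for k in range(1, 8)})
                row.update(n_classified=0.0, poly_sf=0.0, poly_cf=0.0,
                           fixed_derived_sf=0.0, fixed_derived_cf=0.0,
                           ratio_sf_cf=np.nan, ratio_cf_sf=np.nan)
            else:
                f = counts / total
                poly_sf = counts[4] + counts[5] + counts[6]
                poly_cf = counts[2] + counts[3] + counts[6]
                fd_sf = counts[1] + counts[3]
                fd_cf = counts[0] + counts[5]
                row.update({f"freq_{k}": f[k - 1] for k in range(1, 8)})
                row.update(n_classified=total,
                           poly_sf=poly_sf, poly_cf=poly_cf,
                           fixed_derived_sf=fd_sf, fixed_derived_cf=fd_cf,
                           ratio_sf_cf=poly_sf / poly_cf if poly_cf else np.nan,
                           ratio_cf_sf=fd_cf / fd_sf if fd_sf else np.nan)
            if observed is not None:
                from .dating import gof_score
                row["score"] = (np.nan if total == 0
                                else gof_score(counts / total, observed))
            rows.append(row)

        checkpoint(0)
        for year in range(1, p.max_years + 1):
            if p.mig_prob_per_year > 0 and \
                    self.rng.random() < p.mig_prob_per_year:
                freq_cf = self.migrate(freq_cf, freq_sf, p.mig_frac)
            if year % p.g_sf == 0:
                n_new_before = freq_sf.size
                freq_sf = self.step_generation(freq_sf, p.n_sf)
                k = freq_sf.size - n_new_before
                if k:
                    freq_cf = np.concatenate([freq_cf, np.zeros(k)])
            if year % p.g_cf == 0:
                n_new_before = freq_cf.size
                freq_cf = self.step_generation(freq_cf, p.n_cf)
                k = freq_cf.size - n_new_before
                if k:
                    freq_sf = np.concatenate([freq_sf, np.zeros(k)])
            # prune loci absent from or fixed in both populations
            both_lost = (freq_sf == 0.0) & (freq_cf == 0.0)
            both_fixed = (freq_sf == 1.0) & (freq_cf == 1.0)
            gone = both_lost | both_fixed
            if gone.any():
                shared_subs += int(both_fixed.sum())
                keep = ~gone
                freq_sf = freq_sf[keep]
                freq_cf = freq_cf[keep]
            if year % p.checkpoint_years == 0:
                checkpoint(year)

        return Trajectory(params=p, table=pd.DataFrame(rows),
                          shared_substitutions=shared_subs)
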