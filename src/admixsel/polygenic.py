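"""Trait-level (polygenic) selection test.

GWAS hits for a trait are reduced to approximately independent lead
variants by greedy clumping (distance + LD), the trait-increasing allele is
counted across all leads in every population, and the pooled counts are fed
through the same admixture-constrained likelihood-ratio machinery as the
per-variant scan.  Because the per-trait counts are sums over correlated
variants, the chi-squared null does not apply; instead the null is built by
randomly flipping each lead's effect direction and recounting, leaving the
underlying allele frequencies untouched.  Unusually small permutation
p-values indicate directional selection (frequencies too far from the
admixture expectation), unusually large ones stabilizing selection
(frequencies too close).

Only effect directions are used, never effect sizes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .popdata import AdmixtureMatrix, ValidationError
from .scan import _lrt_batch_core

logger = logging.getLogger(__name__)

__all__ = [
    "TraitAssociation",
    "TraitCounts",
    "PolygenicResult",
    "clump",
    "count_trait_alleles",
    "polygenic_test",
    "classify",
    "read_gwas_table",
]

#: GWAS inclusion threshold for lead variants.
DEFAULT_P_THRESHOLD = 1e-8
#: Relaxed threshold for under-powered GWAS.
RELAXED_P_THRESHOLD = 1e-6


@dataclass(frozen=True)
class TraitAssociation:
    """One GWAS association: where, which allele, which way, how significant."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    direction: int  # +1: effect allele increases the trait; -1: decreases
    p: float

    def __post_init__(self):
        if self.direction not in (+1, -1):
            raise ValidationError(
                f"{self.variant_id}: direction must be +1 or -1"
            )
        if not 0.0 < self.p <= 1.0:
            raise ValidationError(f"{self.variant_id}: p must lie in (0, 1]")


@dataclass(frozen=True)
class TraitCounts:
    """Per-lead, per-population trait-increasing allele counts.

    ``inc[l, i]`` counts the trait-increasing allele of lead l in population
    i under the observed directions; ``tot[l, i]`` the non-missing called
    alleles.  Flipping lead l's direction maps inc -> tot - inc, which is
    all the permutation null needs.
    """

    lead_ids: tuple
    inc: np.ndarray
    tot: np.ndarray
    directions: np.ndarray

    @property
    def x(self) -> np.ndarray:
        return self.inc.sum(axis=0).astype(np.int64)

    @property
    def N(self) -> np.ndarray:
        return self.tot.sum(axis=0).astype(np.int64)


@dataclass(frozen=True)
class PolygenicResult:
    trait: str
    x: np.ndarray
    N: np.ndarray
    stat: float
    p_perm: float
    n_perm: int
    seed: Optional[int]
    classification: Optional[str] = None


def read_gwas_table(path) -> list:
    """Read GWAS summary stats TSV: id, chrom, pos, effect_allele, direction, p."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        TraitAssociation(
            variant_id=str(r.id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            effect_allele=str(r.effect_allele),
            direction=int(r.direction),
            p=float(r.p),
        )
        for r in df.itertuples(index=False)
    ]


def clump(
    assocs: Sequence[TraitAssociation],
    ld: pd.DataFrame,
    window: int = 200_000,
    r2_max: float = 0.4,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list:
    """Greedy LD clumping of GWAS associations.

    Repeatedly the smallest-p unclaimed association with p < ``p_threshold``
    becomes a lead and absorbs every unclaimed variant within +-``window``
    bp with r2 > ``r2_max``; pairs without an LD entry count as r2 = 0.
    """
    r2 = {}
    for row in ld.itertuples(index=False):
        r2[(row.id1, row.id2)] = row.r2
        r2[(row.id2, row.id1)] = row.r2
    candidates = sorted(
        (a for a in assocs if a.p < p_threshold), key=lambda a: (a.p, a.variant_id)
    )
    if not candidates:
        logger.warning("clump: no association passes p < %g", p_threshold)
        return []
    claimed: set = set()
    leads = []
    all_sorted = sorted(assocs, key=lambda a: (a.p, a.variant_id))
    for lead in candidates:
        if lead.variant_id in claimed:
            continue
        leads.append(lead)
        claimed.add(lead.variant_id)
        for other in all_sorted:
            if other.variant_id in claimed:
                continue
            if (
                other.chrom == lead.chrom
                and abs(other.pos - lead.pos) <= window
                and r2.get((lead.variant_id, other.variant_id), 0.0) > r2_max
            ):
                claimed.add(other.variant_id)
    return leads


def count_trait_alleles(
    genotype_counts: Mapping[str, tuple],
    leads: Sequence[TraitAssociation],
) -> TraitCounts:
    """Orient per-variant alternate-allele counts to the trait-increasing allele.

    ``genotype_counts`` maps variant id to ``(alt_count, total_count)``
    arrays over populations, with the counts referring to the GWAS effect
    allele.  direction = +1 contributes the alt count, direction = -1 the
    complement N - x.  Leads absent from the genotype table are dropped
    with a warning; variants missing in a population (N=0) contribute
    nothing there.
    """
    inc_rows, tot_rows, kept, dirs = [], [], [], []
    for lead in leads:
        if lead.variant_id not in genotype_counts:
            logger.warning(
                "count_trait_alleles: lead %s absent from genotype table; dropped",
                lead.variant_id,
            )
            continue
        x, N = genotype_counts[lead.variant_id]
        x = np.asarray(x, dtype=np.int64)
        N = np.asarray(N, dtype=np.int64)
        inc_rows.append(x if lead.direction == +1 else N - x)
        tot_rows.append(N)
        kept.append(lead.variant_id)
        dirs.append(lead.direction)
    if not inc_rows:
        raise ValidationError("no lead variant present in the genotype table")
    return TraitCounts(
        lead_ids=tuple(kept),
        inc=np.array(inc_rows),
        tot=np.array(tot_rows),
        directions=np.array(dirs),
    )


def _batch_stats(X: np.ndarray, Ns: np.ndarray, M: AdmixtureMatrix) -> np.ndarray:
    stats_out, _, _, _ = _lrt_batch_core(
        np.ascontiguousarray(X, dtype=float),
        np.ascontiguousarray(Ns, dtype=float),
        M.M,
        1e-7,
        200,
    )
    return stats_out


def polygenic_test(
    counts: TraitCounts,
    M: Optional[AdmixtureMatrix],
    n_perm: int = 1_000_000,
    seed: Optional[int] = None,
    trait: str = "",
    null_mode: str = "flip",
    chunk: int = 100_000,
) -> PolygenicResult:
    """Permutation test of the pooled trait-increasing allele counts.

    The observed statistic is the admixture-constrained LRT on (x, N, M).
    The null re-draws each lead's direction (``null_mode='flip'``:
    independent Rademacher signs; ``'permute'``: a permutation of the
    observed multiset of directions) and recounts x from the stored
    per-variant counts; allele frequencies themselves are never changed.
    p = (1 + #{null >= observed}) / (n_perm + 1).

    In flip mode each lead's sign stream is seeded from (seed, hash of its
    id), so the p-value is exactly invariant to the order of the leads and
    to flipping every observed direction.

    ``M=None`` denotes the saturated single-population case, where the test
    carries no information (stat 0, p 1).
    """
    L, n_pop = counts.inc.shape
    if M is None or n_pop == 1:
        return PolygenicResult(
            trait=trait,
            x=counts.x,
            N=counts.N,
            stat=0.0,
            p_perm=1.0,
            n_perm=n_perm,
            seed=seed,
        )
    if M.n_populations != n_pop:
        raise ValidationError("genotype counts and admixture matrix disagree")
    if L < 2:
        raise ValidationError(
            "permutation null is degenerate with fewer than 2 lead variants"
        )
    if null_mode not in ("flip", "permute"):
        raise ValueError(f"unknown null_mode {null_mode!r}")

    x_obs = counts.x[None, :]
    N = counts.N[None, :]
    obs_stat = float(_batch_stats(x_obs, N, M)[0])

    rng = np.random.default_rng(seed)
    if seed is None:
        seed_eff = int(np.random.SeedSequence().entropy % (2**32))
    else:
        seed_eff = int(seed)
    lead_rngs = [
        np.random.default_rng(
            [
                seed_eff,
                int.from_bytes(
                    hashlib.blake2s(lid.encode(), digest_size=8).digest(), "little"
                ),
            ]
        )
        for lid in counts.lead_ids
    ]
    base = counts.tot - counts.inc  # x under all-flipped directions
    delta = counts.inc - base  # added back for unflipped leads
    n_ge = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        if null_mode == "flip":
            # per-lead streams: the null is independent of lead order
            keep = np.empty((m, L), dtype=bool)
            for l in range(L):
                keep[:, l] = lead_rngs[l].random(m) < 0.5
        else:
            flips_obs = counts.directions == +1
            keep = np.empty((m, L), dtype=bool)
            for r in range(m):
                keep[r] = rng.permutation(flips_obs)
        X = base.sum(axis=0)[None, :] + keep.astype(np.int64) @ delta
        Ns = np.broadcast_to(counts.N, X.shape)
        null_stats = _batch_stats(X, Ns, M)
        n_ge += int(np.sum(null_stats >= obs_stat - 1e-9))
        done += m
    p_perm = (1 + n_ge) / (n_perm + 1)
    return PolygenicResult(
        trait=trait,
        x=counts.x,
        N=counts.N,
        stat=obs_stat,
        p_perm=p_perm,
        n_perm=n_perm,
        seed=seed,
    )


def classify(p_values: Sequence[float], alpha: float = 0.05) -> list:
    """Two-sided Bonferroni classification over N tested traits.

    directional iff p < (alpha/2)/N; stabilizing iff p > 1 - (alpha/2)/N;
    otherwise neutral.  (The symmetric upper cutoff is used for the
    stabilizing tail.)
    """
    n = len(p_values)
    if n < 1:
        raise ValueError("need at least one trait")
    lo = (alpha / 2.0) / n
    hi = 1.0 - lo
    out = []
    for p in p_values:
        if p < lo:
            out.append("directional")
        elif p > hi:
            out.append("stabilizing")
        else:
            out.append("neutral")
    return out
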