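"""Wright-Fisher simulation, power analysis, and synthetic-data generation.

One generation of directional selection moves an allele at frequency f to

    psel = f (1 + s) / (1 + f s)

after which the next generation's 2Ne alleles are a binomial draw with that
success probability.  The same machinery drives three generators:

* ``simulate_scan_dataset`` -- per-variant counts across populations under
  the admixture-constrained null (source frequencies drawn independently,
  mild per-population drift, binomial sampling), optionally with planted
  sweeps in a focal population: the ground truth for scan calibration and
  end-to-end power checks.
* ``power_grid`` -- the detection-power surface over (s, generations),
  rerunning the full scan (genomic control included) on each cell.  Grid
  cells share random inputs (inverse-CDF binomial coupling), so estimated
  power is pathwise monotone in s.
* ``simulate_admixed_dataset`` / ``simulate_time_series`` -- dated,
  ancestry-labelled haploid samples from K independently evolving ancestry
  components, the input of the time-series estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .popdata import AdmixtureMatrix, DatedSample, PopulationCounts, VariantRecord
from .scan import GENOME_WIDE_ALPHA, lrt_batch

__all__ = [
    "WFConfig",
    "PowerRegion",
    "SyntheticScanTruth",
    "AdmixedDataset",
    "selection_update",
    "wf_trajectory",
    "wf_trajectories",
    "drift_frequencies",
    "simulate_scan_dataset",
    "power_grid",
    "simulate_admixed_dataset",
    "simulate_time_series",
]


@dataclass(frozen=True)
class WFConfig:
    """One Wright-Fisher trajectory: 2*Ne alleles, selection s, start f0."""

    Ne: int
    s: float
    f0: float
    generations: int
    seed: int = 0

    def __post_init__(self):
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must lie in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.s <= -1.0:
            raise ValueError("s must exceed -1")


def selection_update(f, s):
    """Deterministic one-generation selection map f -> f(1+s)/(1+fs).

    Monotone in f for fixed s > -1 and in s for fixed f in (0, 1); keeps
    [0, 1] invariant with 0 and 1 absorbing.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("frequency outside [0, 1]")
    denom = 1.0 + f * s
    if np.any(denom <= 0):
        raise ValueError("1 + f*s must be positive")
    out = f * (1.0 + s) / denom
    return float(out) if out.ndim == 0 else out


def wf_trajectory(cfg: WFConfig) -> np.ndarray:
    """Simulate one trajectory; returns frequencies of length generations+1."""
    rng = np.random.default_rng(cfg.seed)
    two_ne = 2 * cfg.Ne
    f = np.empty(cfg.generations + 1)
    f[0] = cfg.f0
    for t in range(cfg.generations):
        f[t + 1] = rng.binomial(two_ne, selection_update(f[t], cfg.s)) / two_ne
    return f


def wf_trajectories(
    Ne: int, s: float, f0, generations: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized trajectories; returns (generations+1, n_reps)."""
    two_ne = 2 * Ne
    f = np.empty((generations + 1, n_reps))
    f[0] = f0
    for t in range(generations):
        f[t + 1] = rng.binomial(two_ne, selection_update(f[t], s)) / two_ne
    return f


def drift_frequencies(
    f: np.ndarray, Ne: int, generations: int, rng: np.random.Generator
) -> np.ndarray:
    """Neutral WF drift applied elementwise for ``generations`` generations."""
    f = np.asarray(f, dtype=float).copy()
    two_ne = 2 * Ne
    for _ in range(generations):
        f = rng.binomial(two_ne, f) / two_ne
    return f


def _coupled_wf_path(
    f0: np.ndarray, s: float, two_ne: int, u: np.ndarray
) -> np.ndarray:
    """WF path driven by given uniforms via the binomial inverse CDF.

    Shape: f0 (V,), u (V, G); returns (G+1, V).  For fixed u the endpoint is
    monotone in s, which is what makes coupled power estimates monotone.
    """
    G = u.shape[1]
    path = np.empty((G + 1, len(f0)))
    path[0] = f0
    f = f0
    for t in range(G):
        p = selection_update(f, s)
        f = sps.binom.ppf(u[:, t], two_ne, p) / two_ne
        path[t + 1] = f
    return path


# ---------------------------------------------------------------------------
# scan-oriented generator


@dataclass(frozen=True)
class SyntheticScanTruth:
    """Ground truth accompanying a simulated counts table."""

    selected_ids: tuple
    s: float
    generations: int
    focal: int
    source_freqs: np.ndarray  # (V, k) pre-drift source frequencies
    true_freqs: np.ndarray  # (V, A+B) post-drift per-population frequencies


@dataclass(frozen=True)
class ScanDataset:
    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    X: np.ndarray
    Ns: np.ndarray
    M: AdmixtureMatrix
    truth: SyntheticScanTruth

    def to_records(self) -> list:
        labels = tuple(self.M.population_labels) or tuple(
            f"POP{i + 1}" for i in range(self.M.n_populations)
        )
        return [
            VariantRecord(
                chrom=str(self.chrom[v]),
                pos=int(self.pos[v]),
                counts=PopulationCounts(
                    variant_id=str(self.ids[v]),
                    x=self.X[v],
                    N=self.Ns[v],
                    labels=labels,
                ),
            )
            for v in range(len(self.ids))
        ]


def _default_sampler(rng: np.random.Generator, size) -> np.ndarray:
    return rng.uniform(0.05, 0.95, size=size)


def simulate_scan_dataset(
    M: AdmixtureMatrix,
    sample_sizes: Sequence[int],
    n_variants: int,
    seed: int,
    n_selected: int = 0,
    s: float = 0.0,
    generations: int = 0,
    focal: int = 0,
    Ne: int = 10_000,
    drift_generations: int = 10,
    freq_sampler: Optional[Callable] = None,
    spacing: int = 5_000,
) -> ScanDataset:
    """Simulate a counts table under the admixture-constrained null.

    Per variant, source frequencies q are drawn independently per source
    (default Uniform(0.05, 0.95)); each population's expected frequency
    M q then drifts independently for ``drift_generations`` Wright-Fisher
    generations at size Ne (the drift that genomic control absorbs), and
    counts are binomial at the stated sample sizes.  The first
    ``n_selected`` variants additionally evolve the focal population's
    frequency under selection ``s`` for ``generations`` generations.
    """
    sampler = freq_sampler or _default_sampler
    rng = np.random.default_rng(seed)
    npop, k = M.n_populations, M.k
    sizes = np.asarray(sample_sizes, dtype=np.int64)
    if len(sizes) != npop:
        raise ValueError("sample_sizes length must match populations in M")
    q = sampler(rng, (n_variants, k))
    f = q @ M.M.T  # (V, npop)
    f = drift_frequencies(f, Ne, drift_generations, rng)
    if n_selected > 0:
        f_focal = f[:n_selected, focal].copy()
        two_ne = 2 * Ne
        for _ in range(generations):
            f_focal = rng.binomial(two_ne, selection_update(f_focal, s)) / two_ne
        f = f.copy()
        f[:n_selected, focal] = f_focal
    X = rng.binomial(sizes[None, :], f)
    Ns = np.broadcast_to(sizes, X.shape).copy()
    ids = np.array([f"vs_{v + 1:07d}" for v in range(n_variants)])
    truth = SyntheticScanTruth(
        selected_ids=tuple(ids[:n_selected]),
        s=s,
        generations=generations,
        focal=focal,
        source_freqs=q,
        true_freqs=f,
    )
    return ScanDataset(
        ids=ids,
        chrom=np.full(n_variants, "1"),
        pos=np.arange(1, n_variants + 1) * spacing,
        X=X,
        Ns=Ns,
        M=M,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# power grid


@dataclass(frozen=True)
class PowerRegion:
    """A synthetic region for power analysis.

    ``sample_sizes`` are total called alleles per population; ``focal`` is
    the population whose frequency is replaced by the simulated endpoint.
    """

    M: AdmixtureMatrix
    sample_sizes: np.ndarray
    focal: int = 0
    Ne: int = 10_000
    drift_generations: int = 10
    freq_sampler: Optional[Callable] = None

    def __post_init__(self):
        object.__setattr__(
            self, "sample_sizes", np.asarray(self.sample_sizes, dtype=np.int64)
        )
        if not 0 <= self.focal < self.M.n_populations:
            raise ValueError("focal population index out of range")


def power_grid(
    region: PowerRegion,
    s_values: Sequence[float],
    generation_values: Sequence[int],
    n_variants: int = 1000,
    maf_min: float = 0.05,
    seed: int = 0,
    n_null: int = 5000,
    alpha: float = GENOME_WIDE_ALPHA,
) -> pd.DataFrame:
    """Estimate scan power over an (s, generations) grid.

    For every cell the focal population's frequency is replaced by the
    endpoint of a selected WF trajectory, the full scan is rerun (statistics
    against the admixture null, genomic control estimated from an
    accompanying null background, genome-wide threshold ``alpha``), and
    power is the detected fraction of the ``n_variants`` selected variants.

    All cells share the underlying uniforms (inverse-CDF binomial
    transitions), so estimates are exactly coupled: monotone in s pathwise,
    and horizons are nested prefixes of a single trajectory per variant.
    """
    s_values = sorted(set(float(s) for s in s_values))
    generation_values = sorted(set(int(g) for g in generation_values))
    g_max = max(generation_values)
    sampler = region.freq_sampler or _default_sampler
    rng = np.random.default_rng(seed)
    M, sizes, focal = region.M, region.sample_sizes, region.focal
    df = M.n_populations - M.k
    two_ne = 2 * region.Ne

    # Null background (shared by every cell) -> genomic-control constant.
    null_ds = simulate_scan_dataset(
        M,
        sizes,
        n_null,
        seed=int(rng.integers(2**31)),
        Ne=region.Ne,
        drift_generations=region.drift_generations,
        freq_sampler=sampler,
    )
    null_stats, _, _, _ = lrt_batch(null_ds.X, null_ds.Ns, M)
    lam = float(np.median(null_stats) / sps.chi2.median(df))
    crit = lam * sps.chi2.isf(alpha, df)  # detection iff stat > crit

    # Baseline frequencies for the focal variants (shared across cells);
    # resample until the focal population satisfies the MAF constraint.
    q = sampler(rng, (n_variants, M.k))
    f_base = drift_frequencies(q @ M.M.T, region.Ne, region.drift_generations, rng)
    bad = np.minimum(f_base[:, focal], 1 - f_base[:, focal]) < maf_min
    while np.any(bad):
        q[bad] = sampler(rng, (int(bad.sum()), M.k))
        f_base[bad] = drift_frequencies(
            q[bad] @ M.M.T, region.Ne, region.drift_generations, rng
        )
        bad = np.minimum(f_base[:, focal], 1 - f_base[:, focal]) < maf_min

    # Non-focal counts drawn once and reused in every cell.
    X_base = rng.binomial(sizes[None, :], f_base)
    u_traj = rng.random((n_variants, g_max)) if g_max > 0 else np.empty((n_variants, 0))
    u_count = rng.random(n_variants)

    rows = []
    for s in s_values:
        path = _coupled_wf_path(f_base[:, focal], s, two_ne, u_traj)
        for g in generation_values:
            f_end = path[g]
            X = X_base.copy()
            X[:, focal] = sps.binom.ppf(u_count, sizes[focal], f_end)
            stats_sel, _, _, _ = lrt_batch(X, np.broadcast_to(sizes, X.shape), M)
            rows.append(
                {
                    "s": s,
                    "generations": g,
                    "power": float(np.mean(stats_sel > crit)),
                    "n": n_variants,
                    "lambda_gc": lam,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# admixture-aware time-series generator


@dataclass(frozen=True)
class PopulationSpec:
    """One sampled population: when, how many haploid samples, what mixture."""

    label: str
    time: int
    n_haploids: int
    admixture: np.ndarray
    is_ancient: bool = True

    def __post_init__(self):
        m = np.asarray(self.admixture, dtype=float)
        object.__setattr__(self, "admixture", m)
        if abs(m.sum() - 1.0) > 1e-6:
            raise ValueError(f"population {self.label}: admixture must sum to 1")


@dataclass(frozen=True)
class AdmixedDataset:
    """Output of :func:`simulate_admixed_dataset` with full ground truth."""

    ids: np.ndarray
    X: np.ndarray  # (V, n_pops) alt counts
    Ns: np.ndarray
    M: AdmixtureMatrix  # realized mean loadings per population
    samples: list  # DatedSample list for the dated variant
    dated_variant: int
    freq: np.ndarray  # (T+1, K, V) true per-ancestry frequencies
    s: np.ndarray  # (T, K) selection schedule (s[t-1] governs t -> t-1)


def _ancestry_trajectories(
    f0: np.ndarray, s: np.ndarray, two_ne: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate (T+1, K, V) frequencies, oldest (t=T) to present (t=0).

    ``s`` has shape (T, K); row t-1 is the coefficient acting on the
    transition from time t to time t-1 (time counted in generations before
    present).
    """
    T, K = s.shape
    V = f0.shape[1]
    f = np.empty((T + 1, K, V))
    f[T] = f0
    for t in range(T, 0, -1):
        for k in range(K):
            p = selection_update(f[t, k], s[t - 1, k])
            f[t - 1, k] = rng.binomial(two_ne, p) / two_ne
    return f


def simulate_admixed_dataset(
    pop_specs: Sequence[PopulationSpec],
    K: int,
    s_schedule=0.0,
    Ne: int = 10_000,
    n_variants: int = 1,
    seed: int = 0,
    concentration: float = 50.0,
    f0_sampler: Optional[Callable] = None,
    dated_variant: int = 0,
) -> AdmixedDataset:
    """Simulate admixed populations over K independently evolving ancestries.

    Each ancestry component follows its own Wright-Fisher trajectory
    (possibly with time- and ancestry-varying selection); each sampled
    haploid allele first draws its ancestry from the individual's Dirichlet
    loadings (centred on the population's target mixture with the given
    concentration), then the allele from that ancestry's frequency at the
    sampling time.  The realized mean loadings per population form the
    admixture matrix exactly as an ADMIXTURE run would be consumed.
    """
    rng = np.random.default_rng(seed)
    T = max(ps.time for ps in pop_specs)
    s = np.asarray(s_schedule, dtype=float)
    if s.ndim > 0:
        T = max(T, s.shape[0])  # the schedule may extend past the oldest sample
    T = max(T, 1)
    if s.ndim == 0:
        s = np.full((T, K), float(s))
    if s.shape != (T, K):
        raise ValueError(f"s_schedule must be scalar or shape ({T}, {K})")
    sampler = f0_sampler or _default_sampler
    f0 = sampler(rng, (K, n_variants))
    freq = _ancestry_trajectories(f0, s, 2 * Ne, rng)

    n_pops = len(pop_specs)
    X = np.zeros((n_variants, n_pops), dtype=np.int64)
    Ns = np.zeros((n_variants, n_pops), dtype=np.int64)
    M_rows = np.zeros((n_pops, K))
    samples: list = []
    for p, ps in enumerate(pop_specs):
        loadings = rng.dirichlet(concentration * ps.admixture + 1e-9, size=ps.n_haploids)
        M_rows[p] = loadings.mean(axis=0)
        # marginal allele probability per individual x variant
        probs = loadings @ freq[ps.time]  # (n, V)
        alleles = rng.random(probs.shape) < probs
        X[:, p] = alleles.sum(axis=0)
        Ns[:, p] = ps.n_haploids
        for i in range(ps.n_haploids):
            samples.append(
                DatedSample(
                    sample_id=f"{ps.label}_{i}",
                    time=ps.time,
                    allele=int(alleles[i, dated_variant]),
                    loadings=loadings[i] / loadings[i].sum(),
                )
            )
    M = AdmixtureMatrix(
        M=M_rows / M_rows.sum(axis=1, keepdims=True),
        population_labels=tuple(ps.label for ps in pop_specs),
    )
    ids = np.array([f"va_{v + 1:06d}" for v in range(n_variants)])
    return AdmixedDataset(
        ids=ids,
        X=X,
        Ns=Ns,
        M=M,
        samples=samples,
        dated_variant=dated_variant,
        freq=freq,
        s=s,
    )


def simulate_time_series(
    Ne: int,
    s,
    T: int,
    samples_per_gen: int,
    K: int = 1,
    f0=0.5,
    proportions: Optional[np.ndarray] = None,
    concentration: float = 50.0,
    seed: int = 0,
):
    """Dense dated samples from K ancestry components over T generations.

    ``samples_per_gen`` haploid individuals are drawn at every generation
    t = 0..T.  Returns ``(samples, freq)`` with freq of shape (T+1, K):
    the true per-ancestry frequency trajectories (index = generations
    before present).
    """
    rng = np.random.default_rng(seed)
    s_arr = np.asarray(s, dtype=float)
    if s_arr.ndim == 0:
        s_arr = np.full((T, K), float(s_arr))
    f0_arr = np.full((K, 1), f0, dtype=float) if np.ndim(f0) == 0 else np.asarray(
        f0, dtype=float
    ).reshape(K, 1)
    freq = _ancestry_trajectories(f0_arr, s_arr, 2 * Ne, rng)[:, :, 0]  # (T+1, K)
    target = np.full(K, 1.0 / K) if proportions is None else np.asarray(proportions)
    samples = []
    for t in range(T + 1):
        if K == 1:
            loadings = np.ones((samples_per_gen, 1))
        else:
            loadings = rng.dirichlet(concentration * target, size=samples_per_gen)
        probs = loadings @ freq[t]
        alleles = rng.random(samples_per_gen) < probs
        for i in range(samples_per_gen):
            samples.append(
                DatedSample(
                    sample_id=f"t{t}_{i}",
                    time=t,
                    allele=int(alleles[i]),
                    loadings=loadings[i] / loadings[i].sum(),
                )
            )
    return samples, freq
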