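"""Per-locus and multi-locus summary statistics on phased haplotypes.

Statistics follow the standard published definitions:

* ``K`` — number of distinct haplotypes in the sample.
* ``S`` — number of segregating (polymorphic) sites.
* ``pi`` — nucleotide diversity: mean pairwise difference per site
  (``pi_locus`` is the same quantity per locus, i.e. in counts).
* Tajima's ``D`` — normalised difference between ``pi_locus`` and
  Watterson's estimator (Tajima 1989).
* Fu's ``Fs`` — ``ln(S'/(1-S'))`` where ``S'`` is the probability, under
  the Ewens sampling formula with theta set to ``pi_locus``, of seeing
  at least the observed number of haplotypes (Fu 1997).
* Fu & Li's ``F*`` — the starred (no-outgroup) statistic contrasting
  total singletons with pairwise diversity, with the corrected
  variance coefficients (Fu & Li 1993; Simonsen et al. 1995).
* Fay & Wu's ``H`` — the unnormalised 2000 version,
  ``pi_locus - theta_H`` with ``theta_H = sum_i 2 S_i i^2 / (n(n-1))``
  over derived-allele counts ``i`` (requires ancestral alleles).

Population differentiation uses the haploid variance-components
(Weir-Cockerham form) F_ST with haplotypes treated as alleles of one
locus, components summed over loci.  All statistics needing S > 0 are
flagged undefined (NaN) on monomorphic data rather than raising.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "LocusData",
    "HaplotypeDataset",
    "LocusStats",
    "SummaryVector",
    "SpectrumResult",
    "locus_stats",
    "fst",
    "spectra",
    "dataset_summary",
    "null_test",
    "ewens_log_pmf",
    "harmonic_number",
    "watterson_expected_s",
    "STAT_NAMES",
]

MISSING_CODE = 4  # allele codes 0..3 are real bases, >=4 is missing (N or gap)
STAT_NAMES = ("K", "S", "pi", "D", "Fs", "Fstar", "H")
BASES = "ACGT"


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class LocusData:
    """One locus: variant positions, allele-code matrix and ancestral states.

    ``alleles`` has shape (n_haplotypes, n_sites), int8 codes indexing
    ``site_alleles``; ``ancestral`` holds the ancestral allele code per
    site (or None when unknown).
    """

    length: int
    positions: np.ndarray
    alleles: np.ndarray
    site_alleles: list[tuple[str, ...]]
    ancestral: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]


@dataclass
class HaplotypeDataset:
    """Phased haplotypes at L unlinked loci, grouped by population.

    Haplotype rows are ordered consistently across loci; haplotype ``2i``
    and ``2i+1`` belong to individual ``samples[i]``.
    """

    loci: list[LocusData]
    samples: list[str]
    populations: np.ndarray  # per-haplotype population label, shape (2*n_samples,)

    def __post_init__(self) -> None:
        n_hap = 2 * len(self.samples)
        if len(self.populations) != n_hap:
            raise ValueError("populations must have one entry per haplotype")
        for i, loc in enumerate(self.loci):
            if loc.n_haplotypes != n_hap:
                raise ValueError(
                    f"locus {i} has {loc.n_haplotypes} haplotypes, expected {n_hap}")

    @property
    def pop_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def mask(self, scope: str) -> np.ndarray:
        if scope == "pooled":
            return np.ones(len(self.populations), dtype=bool)
        return self.populations == scope

    @property
    def has_ancestral(self) -> bool:
        return all(loc.ancestral is not None for loc in self.loci)


@dataclass
class LocusStats:
    K: float
    S: float
    pi: float        # per site
    pi_locus: float  # per locus (counts)
    D: float
    Fs: float
    Fstar: float
    H: float

    def as_dict(self) -> dict[str, float]:
        return {"K": self.K, "S": self.S, "pi": self.pi, "D": self.D,
                "Fs": self.Fs, "Fstar": self.Fstar, "H": self.H}


@dataclass
class SummaryVector:
    """Cross-locus means/SDs of every statistic per scope, plus F_ST.

    ``values`` is a flat named Series (e.g. ``AFR_D_mean``,
    ``pooled_S_sd``, ``fst_global``, ``fst_AFR_EUR``); NaN marks
    statistics undefined on the data (e.g. H without ancestral alleles).
    ``n_defined`` counts the loci contributing to each mean/SD.
    """

    values: pd.Series
    n_defined: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return float(self.values[key])

    def subset(self, names: list[str]) -> np.ndarray:
        return self.values[names].to_numpy(dtype=float)


@dataclass
class SpectrumResult:
    """Observed vs expected allele-frequency spectrum with a 2-class chi2."""

    kind: str  # "MAF" or "DAF"
    bins: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    p: float
    collapsed: tuple[str, str]


# ---------------------------------------------------------------------------
# cached constants
# ---------------------------------------------------------------------------

def harmonic_number(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n} 1/i^power."""
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sum(1.0 / i ** power))


@lru_cache(maxsize=None)
def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1 = harmonic_number(n - 1)
    a2 = harmonic_number(n - 1, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


@lru_cache(maxsize=None)
def _fu_li_fstar_constants(n: int) -> tuple[float, float]:
    """(u_F*, v_F*) with the corrected coefficients."""
    a1 = harmonic_number(n - 1)
    a2 = harmonic_number(n - 1, 2)
    an1 = harmonic_number(n)  # a_{n+1} in the 1/i sum convention up to n
    v = ((2.0 * n ** 3 + 110.0 * n ** 2 - 255.0 * n + 153.0)
         / (9.0 * n ** 2 * (n - 1.0))
         + 2.0 * (n - 1.0) * a1 / n ** 2 - 8.0 * a2 / n) / (a1 ** 2 + a2)
    u = ((4.0 * n ** 2 + 19.0 * n + 3.0 - 12.0 * (n + 1.0) * an1)
         / (3.0 * n * (n - 1.0))) / a1 - v
    return u, v


@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind).

    Log-space row recurrence |s(m+1,k)| = m|s(m,k)| + |s(m,k-1)|, cached
    per sample size (needed up to n = 2x the pooled individual count).
    """
    row = np.full(n + 1, -np.inf)
    row[min(1, n)] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        shifted = np.concatenate(([-np.inf], row[:-1]))
        row = np.logaddexp(math.log(m) + row, shifted)
        row[0] = -np.inf
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    row = _log_stirling_row(n)
    k = np.arange(n + 1, dtype=float)
    log_rising = float(np.sum(np.log(theta + np.arange(n, dtype=float))))
    return row + k * math.log(theta) - log_rising


def watterson_expected_s(n: int, theta_locus: float) -> float:
    """E[S] = a_1 * theta under the standard neutral model.

    ``theta_locus`` is 4*Ne*mu per locus (mu per locus = per-site rate
    times length); ``n`` is the sample size entering the harmonic sum.
    """
    return harmonic_number(n - 1) * theta_locus


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def _void_rows(H: np.ndarray) -> np.ndarray:
    """View matrix rows as void scalars for fast row-wise uniqueness."""
    a = np.ascontiguousarray(H)
    if a.shape[1] == 0:
        return np.zeros(a.shape[0], dtype=np.int64)
    return a.view(np.dtype((np.void, a.dtype.itemsize * a.shape[1]))).ravel()


def _lse(x: np.ndarray) -> float:
    if len(x) == 0:
        return -np.inf
    m = np.max(x)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.exp(x - m).sum()))


def _allele_counts(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts (4, n_sites) of each real allele code per column + valid n."""
    counts = np.empty((4, H.shape[1]), dtype=np.int64)
    for a in range(4):
        counts[a] = (H == a).sum(axis=0)
    n_valid = counts.sum(axis=0)
    return counts, n_valid


def _haplotype_count(H: np.ndarray, merge_missing: bool = True) -> int:
    """Distinct haplotypes; rows with missing merge into a compatible
    resolved row when one exists (else count as their own state)."""
    if H.shape[1] == 0:
        return 1
    has_missing = (H >= MISSING_CODE).any(axis=1)
    if not has_missing.any():
        return max(len(np.unique(_void_rows(H))), 1)
    resolved = np.unique(H[~has_missing], axis=0) if (~has_missing).any() else \
        np.empty((0, H.shape[1]), dtype=H.dtype)
    k = len(resolved)
    unmatched = []
    for row in H[has_missing]:
        ok = row < MISSING_CODE
        if merge_missing and k and np.any((resolved[:, ok] == row[ok]).all(axis=1)):
            continue
        unmatched.append(tuple(row))
    return max(k + len(set(unmatched)), 1)


def locus_stats(
    locus: LocusData | np.ndarray,
    subset: np.ndarray | None = None,
    ancestral: np.ndarray | None = None,
    length: int | None = None,
) -> LocusStats:
    """Compute all per-locus statistics for one population subset.

    ``locus`` may be a :class:`LocusData` or a raw allele-code matrix
    (haplotypes x sites); ``subset`` is a boolean mask or index array
    over haplotypes (default: all).  ``H`` is NaN without ancestral
    alleles; all frequency-based statistics are NaN when S = 0.
    """
    if isinstance(locus, LocusData):
        M = locus.alleles
        ancestral = locus.ancestral if ancestral is None else ancestral
        length = locus.length if length is None else length
    else:
        M = np.asarray(locus, dtype=np.int8)
        if length is None:
            raise ValueError("length required with a raw matrix")
    H = M if subset is None else M[subset]
    n = H.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")

    counts, n_valid = _allele_counts(H)
    seg = (counts > 0).sum(axis=0) >= 2
    S = int(seg.sum())
    K = _haplotype_count(H[:, seg])
    if S == 0:
        return LocusStats(K=K, S=0, pi=0.0, pi_locus=0.0, D=np.nan,
                          Fs=np.nan, Fstar=np.nan, H=np.nan)

    c = counts[:, seg].astype(float)
    nv = n_valid[seg].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = 1.0 - (c * (c - 1.0)).sum(axis=0) / (nv * (nv - 1.0))
    het = np.where(nv >= 2, het, 0.0)
    pi_locus = float(het.sum())
    pi = pi_locus / length

    a1, e1, e2 = _tajima_constants(n)
    theta_w = S / a1
    var_d = e1 * S + e2 * S * (S - 1.0)
    D = (pi_locus - theta_w) / math.sqrt(var_d) if var_d > 0 else np.nan

    # Fu's Fs with theta = pi_locus
    if pi_locus > 0:
        logpmf = ewens_log_pmf(n, pi_locus)
        upper = _lse(logpmf[K:]) if K <= n else -np.inf
        lower = _lse(logpmf[1:K]) if K >= 2 else -np.inf
        Fs = float(upper - lower)
    else:
        Fs = np.nan

    # Fu & Li's F*: total singletons vs pi
    eta_s = int((c == 1.0).sum())
    uF, vF = _fu_li_fstar_constants(n)
    var_f = uF * S + vF * S * S
    Fstar = ((pi_locus - eta_s * (n - 1.0) / n) / math.sqrt(var_f)
             if var_f > 0 else np.nan)

    # Fay & Wu's H (unnormalised), needs ancestral states
    if ancestral is not None:
        anc = np.asarray(ancestral)[seg]
        derived = c.copy()
        cols = np.arange(c.shape[1])
        known = anc < MISSING_CODE
        derived[anc[known], cols[known]] = 0.0  # drop the ancestral allele
        derived[:, ~known] = 0.0
        i_cnt = derived
        internal = (i_cnt >= 1) & (i_cnt <= nv - 1.0)
        theta_h = float((2.0 * i_cnt ** 2 * internal).sum() / (n * (n - 1.0)))
        Hstat = pi_locus - theta_h
    else:
        Hstat = np.nan

    return LocusStats(K=K, S=S, pi=pi, pi_locus=pi_locus, D=D, Fs=Fs,
                      Fstar=Fstar, H=Hstat)


# ---------------------------------------------------------------------------
# F_ST (haploid Weir-Cockerham variance components on haplotype frequencies)
# ---------------------------------------------------------------------------

def _locus_fst_components(H: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float]:
    """(a, a+b) component sums over the haplotype-alleles of one locus."""
    r = len(groups)
    sizes = np.array([len(gi) for gi in groups], dtype=float)
    N = sizes.sum()
    n_c = (N - (sizes ** 2).sum() / N) / (r - 1)
    # haplotype "alleles": index distinct rows over the pooled subset
    pooled = np.concatenate(groups)
    sub = H[pooled]
    _, inv = np.unique(_void_rows(sub), return_inverse=True)
    n_alleles = int(inv.max()) + 1
    # per-group allele frequencies
    starts = np.concatenate([[0], np.cumsum(sizes.astype(int))])
    a_sum = ab_sum = 0.0
    freqs = np.zeros((r, n_alleles))
    for i in range(r):
        codes = inv[starts[i]:starts[i + 1]]
        freqs[i] = np.bincount(codes, minlength=n_alleles) / sizes[i]
    pbar = (sizes[:, None] * freqs).sum(axis=0) / N
    msp = (sizes[:, None] * (freqs - pbar[None, :]) ** 2).sum(axis=0) / (r - 1)
    msg = (sizes[:, None] * freqs * (1.0 - freqs)).sum(axis=0) / (N - r)
    a = (msp - msg) / n_c
    a_sum = float(a.sum())
    ab_sum = float((a + msg).sum())
    return a_sum, ab_sum


def fst(dataset: HaplotypeDataset, pops: list[str] | None = None,
        pairwise: bool = True) -> tuple[float, pd.DataFrame]:
    """Global and pairwise F_ST from haplotype frequencies.

    Haplotypes are treated as alleles of one multi-allelic locus per
    region; Weir-Cockerham variance components are summed over loci (and
    alleles) before taking the ratio.  Populations with fewer than two
    haplotypes are excluded with a warning.
    """
    import warnings

    pops = pops or dataset.pop_names
    masks = {}
    for p in pops:
        idx = np.nonzero(dataset.mask(p))[0]
        if len(idx) < 2:
            warnings.warn(f"population {p} has <2 haplotypes; excluded from F_ST")
            continue
        masks[p] = idx
    names = list(masks)
    if len(names) < 2:
        raise ValueError("F_ST needs at least two populations with >=2 haplotypes")

    def ratio(groups: list[np.ndarray]) -> float:
        a_tot = ab_tot = 0.0
        for loc in dataset.loci:
            a, ab = _locus_fst_components(loc.alleles, groups)
            a_tot += a
            ab_tot += ab
        return a_tot / ab_tot if ab_tot > 0 else 0.0

    global_fst = ratio([masks[p] for p in names])
    pair = pd.DataFrame(np.nan, index=names, columns=names)
    if pairwise:
        for p, q in itertools.combinations(names, 2):
            v = ratio([masks[p], masks[q]])
            pair.loc[p, q] = pair.loc[q, p] = v
    return global_fst, pair


# ---------------------------------------------------------------------------
# allele-frequency spectra
# ---------------------------------------------------------------------------

def spectra(
    dataset: HaplotypeDataset,
    population: str,
    expected_daf: np.ndarray | None = None,
) -> tuple[SpectrumResult, SpectrumResult | None]:
    """Observed vs expected MAF and DAF spectra with two-class chi2 tests.

    The folded (MAF) expectation assumes a constant-size population with
    theta estimated per locus by Watterson's estimator: expected count in
    bin ``i`` is ``theta_W (1/i + 1/(n-i))``, halved at ``i = n-i``; the
    chi-square collapses to singletons vs non-singletons (1 df).  The
    unfolded (DAF) spectrum includes the fixed-derived class and its
    expectation must come from constant-size simulations
    (``expected_daf``, counts or proportions per bin 1..n); its
    chi-square collapses to fixed-derived vs the rest.
    """
    mask = dataset.mask(population)
    n = int(mask.sum())
    half = n // 2
    maf_obs = np.zeros(half, dtype=float)
    maf_exp = np.zeros(half, dtype=float)
    daf_obs = np.zeros(n, dtype=float) if dataset.has_ancestral else None

    phi = np.array([1.0 / i + 1.0 / (n - i) for i in range(1, half + 1)])
    if n % 2 == 0:
        phi[-1] /= 2.0
    a1 = harmonic_number(n - 1)

    for loc in dataset.loci:
        counts, n_valid = _allele_counts(loc.alleles[mask])
        seg = (counts > 0).sum(axis=0) >= 2
        if seg.any():
            c = counts[:, seg]
            minor = c.sum(axis=0) - c.max(axis=0)
            minor = np.clip(minor, 1, half)
            maf_obs += np.bincount(minor - 1, minlength=half)[:half]
            theta_w = seg.sum() / a1
            maf_exp += theta_w * phi
        if daf_obs is not None and loc.ancestral is not None:
            anc = loc.ancestral
            c_all, nv = _allele_counts(loc.alleles[mask])
            for a in range(4):
                is_derived = (anc < MISSING_CODE) & (anc != a)
                cnt = c_all[a]
                sel = is_derived & (cnt >= 1) & (cnt <= n)
                if sel.any():
                    daf_obs += np.bincount(cnt[sel] - 1, minlength=n)[:n]

    def two_class(obs2: np.ndarray, exp2: np.ndarray) -> tuple[float, float]:
        if np.any(exp2 <= 0):
            raise ValueError("zero expected count in a collapsed chi2 class")
        chi2 = float(((obs2 - exp2) ** 2 / exp2).sum())
        return chi2, float(sps.chi2.sf(chi2, df=1))

    s_tot = maf_obs.sum()
    chi2_m, p_m = two_class(
        np.array([maf_obs[0], s_tot - maf_obs[0]]),
        np.array([maf_exp[0], maf_exp.sum() - maf_exp[0]]),
    )
    maf = SpectrumResult("MAF", np.arange(1, half + 1), maf_obs, maf_exp,
                         chi2_m, p_m, ("singletons", "non-singletons"))

    daf = None
    if daf_obs is not None and expected_daf is not None:
        exp = np.asarray(expected_daf, dtype=float)
        if len(exp) != n:
            raise ValueError(f"expected_daf must have {n} bins")
        exp = exp / exp.sum() * daf_obs.sum()
        chi2_d, p_d = two_class(
            np.array([daf_obs[-1], daf_obs[:-1].sum()]),
            np.array([exp[-1], exp[:-1].sum()]),
        )
        daf = SpectrumResult("DAF", np.arange(1, n + 1), daf_obs, exp,
                             chi2_d, p_d, ("fixed-derived", "non-fixed"))
    return maf, daf


def observed_daf_counts(dataset: HaplotypeDataset, population: str) -> np.ndarray:
    """Derived-allele-count spectrum (bins 1..n, incl. fixed) for one population."""
    mask = dataset.mask(population)
    n = int(mask.sum())
    out = np.zeros(n, dtype=float)
    for loc in dataset.loci:
        if loc.ancestral is None:
            continue
        counts, _ = _allele_counts(loc.alleles[mask])
        anc = loc.ancestral
        for a in range(4):
            sel = (anc < MISSING_CODE) & (anc != a) & (counts[a] >= 1)
            if sel.any():
                out += np.bincount(counts[a][sel] - 1, minlength=n)[:n]
    return out


# ---------------------------------------------------------------------------
# dataset summaries
# ---------------------------------------------------------------------------

def dataset_summary(
    dataset: HaplotypeDataset,
    scopes: tuple[str, ...] | None = None,
    with_fst: bool = True,
    fst_pairwise: bool = True,
) -> SummaryVector:
    """Cross-locus means and SDs of every statistic, per scope, plus F_ST.

    Scopes default to each population plus ``pooled`` (all samples
    merged, the set used for the archaic-stage fit).  Loci on which a
    statistic is undefined are excluded from its mean/SD;
    ``n_defined`` records how many loci contributed.  With a single
    locus the SDs are NaN.
    """
    if scopes is None:
        scopes = (*dataset.pop_names, "pooled")
    values: dict[str, float] = {}
    n_def: dict[str, int] = {}
    for scope in scopes:
        mask = dataset.mask(scope)
        rows = [locus_stats(loc, subset=mask).as_dict() for loc in dataset.loci]
        tab = pd.DataFrame(rows)
        for stat in STAT_NAMES:
            col = tab[stat].to_numpy(dtype=float)
            ok = ~np.isnan(col)
            key = f"{scope}_{stat}"
            n_def[key] = int(ok.sum())
            values[f"{key}_mean"] = float(col[ok].mean()) if ok.any() else np.nan
            values[f"{key}_sd"] = (float(col[ok].std(ddof=1))
                                   if ok.sum() > 1 else np.nan)
    if with_fst and len(dataset.pop_names) >= 2:
        g, pair = fst(dataset, pairwise=fst_pairwise)
        values["fst_global"] = g
        if fst_pairwise:
            for p, q in itertools.combinations(pair.index, 2):
                values[f"fst_{p}_{q}"] = float(pair.loc[p, q])
    return SummaryVector(values=pd.Series(values), n_defined=n_def)


# ---------------------------------------------------------------------------
# empirical null-model tests
# ---------------------------------------------------------------------------

def empirical_pvalues(observed: pd.Series, null_table: pd.DataFrame) -> pd.DataFrame:
    """Two-sided empirical p-values with add-one correction, per statistic.

    ``p = 2 * min(r_low, r_high) / (n + 1)`` where ``r_low``/``r_high``
    count null values <= / >= the observed one (capped at 1).  The
    reported direction says whether the observed value sits above or
    below the null median.
    """
    out = []
    n = len(null_table)
    for name in observed.index:
        if name not in null_table.columns:
            continue
        null = null_table[name].to_numpy(dtype=float)
        null = null[~np.isnan(null)]
        obs = float(observed[name])
        if np.isnan(obs) or len(null) == 0:
            out.append({"statistic": name, "p": np.nan, "direction": "NA"})
            continue
        r_low = int((null <= obs).sum()) + 1
        r_high = int((null >= obs).sum()) + 1
        p = min(1.0, 2.0 * min(r_low, r_high) / (len(null) + 1))
        direction = "increased" if obs > np.median(null) else "reduced"
        out.append({"statistic": name, "p": p, "direction": direction})
    return pd.DataFrame(out).set_index("statistic")


def null_test(
    observed: SummaryVector,
    priors=None,
    n_sims: int = 1000,
    recomb_modes: tuple[str, ...] = ("none", "gamma", "fixed_10x"),
    rng_seed: int = 0,
    null_tables: dict[str, pd.DataFrame] | None = None,
    **sim_kwargs,
) -> pd.DataFrame:
    """Test every summary statistic against the constant-size null model.

    For each recombination treatment a table of null summary vectors is
    simulated (or supplied via ``null_tables``); per statistic the
    two-sided empirical p-value is computed and the most conservative
    (largest) p across treatments is reported, along with the direction
    of the deviation.
    """
    if null_tables is None:
        if n_sims < 100:
            raise ValueError("n_sims < 100 gives too coarse a p resolution")
        from . import coalsim  # lazy: coalsim imports this module

        null_tables = {
            mode: coalsim.simulate_null_reference(
                n_sims=n_sims, recomb_mode=mode, rng_seed=rng_seed + i,
                priors=priors, **sim_kwargs)
            for i, mode in enumerate(recomb_modes)
        }
    per_mode = {m: empirical_pvalues(observed.values, t)
                for m, t in null_tables.items()}
    first = next(iter(per_mode.values()))
    merged = first.copy()
    merged["p"] = np.nanmax(
        np.column_stack([t["p"].to_numpy(dtype=float) for t in per_mode.values()]),
        axis=1)
    return merged
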