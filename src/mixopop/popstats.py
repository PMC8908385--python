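"""Diversity and differentiation statistics under assumed ploidy.

Implements gene diversity Hs = 1 - sum(p^2) and the effective number of
alleles EN = 1/(1 - Hs), Nei's Gst and Jost's D over pairs of populations,
a four-level hierarchical AMOVA (alleles within individuals / among
individuals within populations / among populations within groups / among
groups) yielding F_IT, F_IS, F_SC and F_CT by the method of moments with
unequal-size coefficients, and a PCA on within-individual relative allele
frequencies.

Unknown allele dosage is handled upstream: frequencies come from the
dosage-correcting EM (``mixopop.ploidy``), while the AMOVA resolves each
ambiguous cell by a uniform draw over the compatible dosage multisets,
repeated over R replicates whose spread is reported alongside the
per-locus spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ploidy import (
    AlleleFrequencyEstimate,
    PloidyCoding,
    em_allele_frequencies,
    enumerate_compatible_genotypes,
)

__all__ = [
    "gene_diversity",
    "effective_alleles",
    "population_frequencies",
    "diversity_table",
    "pairwise_differentiation",
    "PairwiseMatrix",
    "Hierarchy",
    "AmovaResult",
    "amova",
    "pca_genotypes",
    "PcaResult",
]


def gene_diversity(freqs) -> float:
    """Hs = 1 - sum p_i^2 (expected heterozygosity under random union)."""
    p = np.asarray(freqs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequency vector sums to {p.sum()}, not 1")
    return float(1.0 - np.sum(p * p))


def effective_alleles(hs: float) -> float:
    """EN = 1/(1 - Hs): equifrequent alleles giving the same diversity."""
    if not 0.0 <= hs < 1.0:
        raise ValueError(f"Hs must lie in [0, 1), got {hs}")
    return 1.0 / (1.0 - hs)


def population_frequencies(
    ds, coding: PloidyCoding, tol: float = 1e-8, max_iter: int = 10000
) -> dict[str, dict[str, AlleleFrequencyEstimate]]:
    """EM frequency estimates for every population x locus with data."""
    out: dict[str, dict[str, AlleleFrequencyEstimate]] = {}
    for pop, members in ds.by_population().items():
        per_locus: dict[str, AlleleFrequencyEstimate] = {}
        for locus in ds.locus_names:
            phenotypes = [
                coding.retained(ind.individual_id, locus)
                for ind in members
                if coding.retained(ind.individual_id, locus) is not None
            ]
            if phenotypes:
                per_locus[locus] = em_allele_frequencies(
                    phenotypes, coding.assumed_ploidy, tol=tol, max_iter=max_iter
                )
        out[pop] = per_locus
    return out


def diversity_table(
    ds,
    coding: PloidyCoding,
    freqs: dict[str, dict[str, AlleleFrequencyEstimate]] | None = None,
) -> pd.DataFrame:
    """Per-population diversity: N, per-locus mean/SD of Hs, EN from mean Hs.

    EN = 1/(1 - Hs) is applied to the locus-averaged Hs, so the EN/Hs
    bijection holds exactly at that averaging level.  Populations with zero
    scored loci are excluded with a warning.
    """
    if freqs is None:
        freqs = population_frequencies(ds, coding)
    by_pop = ds.by_population()
    rows = []
    for pop in ds.population_codes:
        per_locus = freqs.get(pop, {})
        if not per_locus:
            warnings.warn(f"population {pop!r} has no scored loci; excluded", stacklevel=2)
            continue
        hs_values = np.array([gene_diversity(est.probs) for est in per_locus.values()])
        hs_mean = float(hs_values.mean())
        rows.append(
            {
                "population": pop,
                "N": len(by_pop[pop]),
                "n_loci": len(per_locus),
                "Hs": hs_mean,
                "Hs_sd": float(hs_values.std(ddof=1)) if len(hs_values) > 1 else 0.0,
                "EN": effective_alleles(hs_mean),
                "assumed_ploidy": coding.assumed_ploidy,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PairwiseMatrix:
    statistic: str  # "Gst" | "JostD"
    populations: list[str]
    values: pd.DataFrame  # symmetric, zero diagonal
    per_locus: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)


def _aligned_pair(est_a: AlleleFrequencyEstimate, est_b: AlleleFrequencyEstimate):
    alleles = sorted(set(est_a.alleles) | set(est_b.alleles))
    pa = np.array([est_a.as_dict().get(a, 0.0) for a in alleles])
    pb = np.array([est_b.as_dict().get(a, 0.0) for a in alleles])
    return pa, pb


def _pair_locus_stats(pa: np.ndarray, pb: np.ndarray) -> tuple[float, float]:
    hs_bar = 0.5 * (gene_diversity(pa) + gene_diversity(pb))
    ht = gene_diversity(0.5 * (pa + pb))
    return hs_bar, ht


def pairwise_differentiation(
    freqs: dict[str, dict[str, AlleleFrequencyEstimate]],
    statistic: str = "Gst",
) -> PairwiseMatrix:
    """Pairwise Nei's Gst or Jost's D over populations from EM frequencies.

    Per locus for a pair: Hs_bar is the mean within-population gene
    diversity and Ht the diversity of the mean frequency vector;
    Gst = (Ht - Hs_bar)/Ht and D = 2 (Ht - Hs_bar)/(1 - Hs_bar) (pairwise
    factor k/(k-1) = 2).  Multi-locus Gst is the ratio of locus averages,
    multi-locus D the harmonic mean of per-locus D (any non-positive locus
    value sends the harmonic mean to 0).  Ht = 0 defines the statistic as 0.
    """
    if statistic not in ("Gst", "JostD"):
        raise ValueError(f"statistic must be 'Gst' or 'JostD', got {statistic!r}")
    pops = list(freqs)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    per_locus_store: dict[tuple[str, str], dict[str, float]] = {}
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            shared = sorted(set(freqs[a]) & set(freqs[b]))
            hs_list, ht_list, d_list = [], [], []
            locus_vals: dict[str, float] = {}
            for locus in shared:
                pa, pb = _aligned_pair(freqs[a][locus], freqs[b][locus])
                hs_bar, ht = _pair_locus_stats(pa, pb)
                hs_list.append(hs_bar)
                ht_list.append(ht)
                if statistic == "Gst":
                    locus_vals[locus] = 0.0 if ht == 0 else (ht - hs_bar) / ht
                else:
                    d = 0.0 if ht == 0 else 2.0 * (ht - hs_bar) / (1.0 - hs_bar)
                    d_list.append(d)
                    locus_vals[locus] = d
            if not shared:
                value = np.nan
            elif statistic == "Gst":
                ht_sum = float(np.sum(ht_list))
                value = 0.0 if ht_sum == 0 else (ht_sum - float(np.sum(hs_list))) / ht_sum
            else:
                d_arr = np.array(d_list)
                # harmonic mean; it tends to 0 as any locus value tends to 0
                if np.any(d_arr <= 0.0):
                    value = 0.0
                else:
                    value = float(len(d_arr) / np.sum(1.0 / d_arr))
            mat.loc[a, b] = mat.loc[b, a] = value
            per_locus_store[(a, b)] = locus_vals
    return PairwiseMatrix(
        statistic=statistic, populations=pops, values=mat, per_locus=per_locus_store
    )


@dataclass
class Hierarchy:
    """Group assignment for the AMOVA: population code -> group label."""

    group_of: dict[str, str]
    name: str = "hierarchy"

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pop, grp in self.group_of.items():
            out.setdefault(grp, []).append(pop)
        return out


@dataclass
class AmovaResult:
    """Variance components and hierarchical F-statistics.

    Components (method of moments, may be negative): ``sigma2`` maps the
    four levels — among_groups, among_pops_within_groups,
    among_individuals_within_pops, within_individuals — to their estimates
    combined over loci (sums of squares pooled across loci) and averaged
    over dosage-resolution replicates.  ``f_stats`` holds F_CT, F_SC, F_IS,
    F_IT with SDs over loci and over replicates; ``pct_variance`` sums to
    100.
    """

    assumed_ploidy: int
    hierarchy: str
    n_replicates: int
    sigma2: dict[str, float]
    pct_variance: dict[str, float]
    f_stats: dict[str, float]
    f_sd_loci: dict[str, float]
    f_sd_replicates: dict[str, float]
    per_locus_f: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        levels = [
            ("within_individuals", "F_IT"),
            ("among_individuals_within_pops", "F_IS"),
            ("among_pops_within_groups", "F_SC"),
            ("among_groups", "F_CT"),
        ]
        rows = []
        for level, fname in levels:
            rows.append(
                {
                    "source": level,
                    "F_statistic": fname,
                    "F_value": self.f_stats[fname],
                    "F_sd_loci": self.f_sd_loci[fname],
                    "F_sd_replicates": self.f_sd_replicates[fname],
                    "sigma2": self.sigma2[level],
                    "pct_variance": self.pct_variance[level],
                }
            )
        return pd.DataFrame(rows)


_LEVELS = (
    "among_groups",
    "among_pops_within_groups",
    "among_individuals_within_pops",
    "within_individuals",
)


def _ss_from_counts(counts: np.ndarray) -> float:
    """AMOVA sum of squares of a set of gene copies with 0/1 distances:
    (1/n) * sum_{i<j} d_ij = (n - sum_a c_a^2 / n) / 2."""
    n = counts.sum()
    if n == 0:
        return 0.0
    return float((n - np.sum(counts.astype(float) ** 2) / n) / 2.0)


def _locus_components(
    group_of_ind: np.ndarray,
    pop_of_ind: np.ndarray,
    copies: np.ndarray,
    m: int,
    n_alleles: int,
):
    """Variance components for one locus.

    ``copies`` is an (n_scored, n_alleles) integer matrix of allele copy
    counts per scored individual (each row sums to m); group/pop arrays give
    the integer group and population index of each scored individual.
    Returns (sigma2 vector in _LEVELS order, df vector, SS vector,
    coefficient tuple) or None when no individual is scored.
    """
    n_ind = copies.shape[0]
    if n_ind == 0:
        return None
    N = m * n_ind
    pops = np.unique(pop_of_ind)
    groups = np.unique(group_of_ind)
    P, G = len(pops), len(groups)

    total_counts = copies.sum(axis=0)
    ss_total = _ss_from_counts(total_counts)
    ss_wi = sum(_ss_from_counts(copies[i]) for i in range(n_ind))

    pop_counts = {p: copies[pop_of_ind == p].sum(axis=0) for p in pops}
    ss_within_pop = sum(_ss_from_counts(c) for c in pop_counts.values())
    group_counts = {g: copies[group_of_ind == g].sum(axis=0) for g in groups}
    ss_within_group = sum(_ss_from_counts(c) for c in group_counts.values())

    ss = np.array(
        [
            ss_total - ss_within_group,  # among groups
            ss_within_group - ss_within_pop,  # among pops within groups
            ss_within_pop - ss_wi,  # among individuals within pops
            ss_wi,  # within individuals
        ]
    )
    df = np.array([G - 1, P - G, n_ind - P, N - n_ind], dtype=float)

    # unequal-size coefficients; copies per individual are constant (= m),
    # so the individual-level coefficient is exactly m
    n_p = np.array([m * np.sum(pop_of_ind == p) for p in pops], dtype=float)
    n_g = np.array([m * np.sum(group_of_ind == g) for g in groups], dtype=float)
    pop_group = np.array(
        [group_of_ind[pop_of_ind == p][0] for p in pops]
    )  # group index of each pop
    sum_np2_over_ng = sum(
        np.sum(n_p[pop_group == g] ** 2) / n_g[gi]
        for gi, g in enumerate(groups)
    )
    k3 = (N - sum_np2_over_ng) / (P - G) if P > G else np.nan
    k5 = (sum_np2_over_ng - np.sum(n_p**2) / N) / (G - 1) if G > 1 else np.nan
    k6 = (N - np.sum(n_g**2) / N) / (G - 1) if G > 1 else np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        ms = np.where(df > 0, ss / np.where(df > 0, df, 1.0), np.nan)
    ms_ag, ms_ap, ms_ai, ms_wi = ms
    s_w = ms_wi
    s_c = (ms_ai - s_w) / m
    s_b = (ms_ap - s_w - m * s_c) / k3
    s_a = (ms_ag - s_w - m * s_c - k5 * s_b) / k6
    sigma = np.array([s_a, s_b, s_c, s_w])
    return sigma, df, ss, (k3, k5, k6, m)


def _f_from_sigma(sigma: np.ndarray) -> dict[str, float]:
    s_a, s_b, s_c, s_w = sigma
    total = sigma.sum()
    if total == 0 or not np.isfinite(total):
        return {k: np.nan for k in ("F_CT", "F_SC", "F_IS", "F_IT")}
    def ratio(num, denom):
        if denom == 0:
            # 0/0 (every lower level monomorphic) is no differentiation
            return 0.0 if num == 0 else np.nan
        return num / denom

    return {
        "F_CT": s_a / total,
        "F_SC": ratio(s_b, s_b + s_c + s_w),
        "F_IS": ratio(s_c, s_c + s_w),
        "F_IT": (s_a + s_b + s_c) / total,
    }


def _resolve_dosage(retained: tuple[int, ...], m: int, rng: np.random.Generator):
    """Uniform draw over compatible dosage multisets; deterministic when
    there is only one."""
    if len(retained) == m:
        return retained
    genos = enumerate_compatible_genotypes(retained, m)
    if len(genos) == 1:
        return genos[0]
    return genos[int(rng.integers(len(genos)))]


def amova(
    ds,
    coding: PloidyCoding,
    hierarchy: Hierarchy,
    replicates: int = 10,
    seed: int = 0,
) -> AmovaResult:
    """Four-level AMOVA at the coding's assumed ploidy.

    Each individual is expanded to m allele copies per locus; ambiguous
    dosage is resolved per replicate by a uniform draw over the compatible
    multisets.  Squared distance between copies is 0/1 identity in state.
    Components are method-of-moments with the standard unequal-size
    coefficients; loci are combined by pooling sums of squares and degrees
    of freedom (df-weighted coefficients) before forming components.  No
    permutation p-values are produced: testing groupings derived from the
    data itself would be circular.
    """
    m = coding.assumed_ploidy
    pops_in_data = ds.population_codes
    missing_pops = [p for p in pops_in_data if p not in hierarchy.group_of]
    if missing_pops:
        raise ValueError(f"hierarchy does not assign populations: {missing_pops}")
    groups = hierarchy.groups()
    used_groups = {
        g: [p for p in members if p in pops_in_data] for g, members in groups.items()
    }
    used_groups = {g: ps for g, ps in used_groups.items() if ps}
    if len(used_groups) < 2:
        raise ValueError("AMOVA needs at least 2 groups with data")
    singletons = [g for g, ps in used_groups.items() if len(ps) < 2]
    if singletons:
        raise ValueError(
            f"groups with a single population: {singletons}; the among-populations "
            "component is undefined there — merge the group with another or drop it"
        )

    pop_index = {p: i for i, p in enumerate(pops_in_data)}
    group_labels = sorted(used_groups)
    group_index = {g: i for i, g in enumerate(group_labels)}
    ind_pop = np.array([pop_index[ind.population] for ind in ds.individuals])
    ind_group = np.array(
        [group_index[hierarchy.group_of[ind.population]] for ind in ds.individuals]
    )

    # per locus, list of (individual positions, allele index map, retained sets)
    loci = ds.locus_names
    rep_sigmas = []  # per replicate: combined sigma vector
    rep_fs = []
    locus_f_records = []
    rep_locus_sigmas = []  # per replicate: list of per-locus sigma vectors

    for r in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, r]))
        ss_sum = np.zeros(4)
        df_sum = np.zeros(4)
        coef_acc = np.zeros(4)  # df-weighted k3, k5, k6, m
        coef_w = np.zeros(4)
        locus_sigmas = []
        for locus in loci:
            scored_rows = []
            retained_sets = []
            for i, ind in enumerate(ds.individuals):
                ret = coding.retained(ind.individual_id, locus)
                if ret is not None:
                    scored_rows.append(i)
                    retained_sets.append(ret)
            if not scored_rows:
                continue
            alleles = sorted(set(a for ret in retained_sets for a in ret))
            aidx = {a: j for j, a in enumerate(alleles)}
            copies = np.zeros((len(scored_rows), len(alleles)), dtype=np.int64)
            for row, ret in enumerate(retained_sets):
                geno = _resolve_dosage(ret, m, rng)
                for a in geno:
                    copies[row, aidx[a]] += 1
            res = _locus_components(
                ind_group[scored_rows], ind_pop[scored_rows], copies, m, len(alleles)
            )
            if res is None:
                continue
            sigma_l, df_l, ss_l, (k3, k5, k6, _) = res
            locus_sigmas.append(sigma_l)
            locus_f_records.append(
                {"replicate": r, "locus": locus, **_f_from_sigma(sigma_l)}
            )
            ss_sum += ss_l
            df_sum += df_l
            # df-weights: k3 scales MS_among-pops, k5/k6 MS_among-groups,
            # m MS_among-individuals
            coef_df = (df_l[1], df_l[0], df_l[0], df_l[2])
            for j, k in enumerate((k3, k5, k6, m)):
                if np.isfinite(k):
                    w = max(coef_df[j], 1.0)
                    coef_acc[j] += k * w
                    coef_w[j] += w

        if not np.any(df_sum > 0):
            raise ValueError("no scored loci for AMOVA")
        k3c, k5c, k6c, mc = (
            coef_acc[0] / coef_w[0] if coef_w[0] else np.nan,
            coef_acc[1] / coef_w[1] if coef_w[1] else np.nan,
            coef_acc[2] / coef_w[2] if coef_w[2] else np.nan,
            coef_acc[3] / coef_w[3] if coef_w[3] else float(m),
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            ms = np.where(df_sum > 0, ss_sum / np.where(df_sum > 0, df_sum, 1.0), np.nan)
        ms_ag, ms_ap, ms_ai, ms_wi = ms
        s_w = ms_wi
        s_c = (ms_ai - s_w) / mc
        s_b = (ms_ap - s_w - mc * s_c) / k3c
        s_a = (ms_ag - s_w - mc * s_c - k5c * s_b) / k6c
        sigma = np.array([s_a, s_b, s_c, s_w])
        rep_sigmas.append(sigma)
        rep_fs.append(_f_from_sigma(sigma))
        rep_locus_sigmas.append(locus_sigmas)

    sigma_mean = np.mean(rep_sigmas, axis=0)
    total = sigma_mean.sum()
    if total == 0 or not np.isfinite(total):
        warnings.warn(
            "total variance is zero; F-statistics undefined (NaN)", stacklevel=2
        )
        pct = {lvl: np.nan for lvl in _LEVELS}
    else:
        pct = {lvl: 100.0 * sigma_mean[i] / total for i, lvl in enumerate(_LEVELS)}

    f_names = ("F_CT", "F_SC", "F_IS", "F_IT")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN replicate slices
        f_mean = {k: float(np.nanmean([f[k] for f in rep_fs])) for k in f_names}
        f_sd_rep = {
            k: float(np.nanstd([f[k] for f in rep_fs], ddof=1)) if replicates > 1 else 0.0
            for k in f_names
        }
    locus_df = pd.DataFrame(locus_f_records)
    f_sd_loci = {}
    for k in f_names:
        if len(locus_df) > 1:
            per_locus = locus_df.groupby("locus")[k].mean()
            f_sd_loci[k] = float(per_locus.std(ddof=1)) if len(per_locus) > 1 else 0.0
        else:
            f_sd_loci[k] = 0.0

    return AmovaResult(
        assumed_ploidy=m,
        hierarchy=hierarchy.name,
        n_replicates=replicates,
        sigma2={lvl: float(sigma_mean[i]) for i, lvl in enumerate(_LEVELS)},
        pct_variance={lvl: float(pct[lvl]) for lvl in _LEVELS},
        f_stats=f_mean,
        f_sd_loci=f_sd_loci,
        f_sd_replicates=f_sd_rep,
        per_locus_f=locus_df if len(locus_df) else None,
    )


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # individuals x axes
    eigenvalues: np.ndarray  # non-increasing
    pct_variance: np.ndarray
    columns: list[tuple[str, int]]  # (locus, allele) dictionary


def pca_genotypes(ds, coding: PloidyCoding, n_axes: int = 10) -> PcaResult:
    """PCA on the individual x (locus, allele) matrix of within-individual
    relative allele frequencies.

    Each retained allele at a locus is weighted 1/|retained set|; a missing
    locus is imputed with the individual's population column means (falling
    back to the global mean when the whole population lacks the locus).
    Columns are centered; coordinates come from the SVD of the centered
    matrix, so eigenvalues are non-increasing and coordinates are centered
    per axis.
    """
    keep = [
        ind
        for ind in ds.individuals
        if any(coding.retained(ind.individual_id, locus) is not None for locus in ds.locus_names)
    ]
    dropped = len(ds.individuals) - len(keep)
    if dropped:
        warnings.warn(f"{dropped} all-missing individuals dropped from PCA", stacklevel=2)
    if len(keep) < 2:
        raise ValueError("PCA needs at least 2 individuals with data")

    columns: list[tuple[str, int]] = []
    for locus in ds.locus_names:
        alleles = sorted(
            {
                a
                for ind in keep
                for a in (coding.retained(ind.individual_id, locus) or ())
            }
        )
        columns.extend((locus, a) for a in alleles)
    col_index = {col: j for j, col in enumerate(columns)}

    n = len(keep)
    X = np.zeros((n, len(columns)))
    observed = np.zeros((n, len(columns)), dtype=bool)
    for i, ind in enumerate(keep):
        for locus in ds.locus_names:
            ret = coding.retained(ind.individual_id, locus)
            if ret is None:
                continue
            w = 1.0 / len(ret)
            for a in ret:
                X[i, col_index[(locus, a)]] = w
            for a in {al for (lo, al) in columns if lo == locus}:
                observed[i, col_index[(locus, a)]] = True

    # population-mean imputation of missing loci
    pop_of = np.array([ind.population for ind in keep])
    global_mean = np.zeros(len(columns))
    for j in range(len(columns)):
        obs_j = observed[:, j]
        global_mean[j] = X[obs_j, j].mean() if obs_j.any() else 0.0
    for pop in np.unique(pop_of):
        rows = pop_of == pop
        for j in range(len(columns)):
            obs_j = observed[rows, j]
            fill = X[rows][obs_j, j].mean() if obs_j.any() else global_mean[j]
            block = X[rows, j]
            block[~obs_j] = fill
            X[rows, j] = block

    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: among near-maximal-magnitude loadings pick the one
    # with the smallest column index and make it positive (fp-tie safe)
    for k in range(len(S)):
        mags = np.abs(Vt[k])
        top = mags.max()
        if top == 0:
            continue
        j = int(np.flatnonzero(mags >= top - 1e-9 * max(top, 1.0))[0])
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    eig = S**2 / max(n - 1, 1)
    n_axes = min(n_axes, len(S))
    coords = U[:, :n_axes] * S[:n_axes]
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    frame = pd.DataFrame(
        coords,
        index=[ind.individual_id for ind in keep],
        columns=[f"PC{k + 1}" for k in range(n_axes)],
    )
    return PcaResult(
        coordinates=frame,
        eigenvalues=eig[:n_axes],
        pct_variance=pct[:n_axes],
        columns=columns,
    )
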