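"""Synthetic cohorts with the statistical structure of plasma cfDNA studies.

Generates everything the pipeline consumes, with known ground truth: a
tissue methylation atlas with planted tissue-specific regions; per-sample
CpG call tables whose window-level expectation is the atlas-mixture product
A.x plus planted group-specific DMR shifts in enhancer/promoter windows;
fragment-length draws with the canonical 167-bp mode, ~320-bp dinucleosomal
peak and 10-bp sub-modal periodicity; Poisson bin counts around planted copy
segments; and binomial spike-in conversion counts.

Defaults encode the study conditions the pipeline is tested under: global
CpG methylation centred on 0.755 (a bimodal beta mixture, most CpGs near 0
or 1), blood-dominant tissue mixtures, and binomial read sampling at a
configurable mean coverage.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import window_id

DEFAULT_GLOBAL_MEAN = 0.755  # mean CpG methylation of control plasma
_MU_LOW, _MU_HIGH = 0.08, 0.92  # bimodal mixture component means


# ---------------------------------------------------------------- atlas

@dataclass(frozen=True)
class SyntheticAtlasTruth:
    """Ground-truth tissue atlas: region x tissue methylation plus the planted
    tissue-specific region sets."""

    tissue_names: tuple[str, ...]
    region_methylation: pd.DataFrame = field(repr=False)
    specific_regions: dict[str, set[str]] = field(repr=False)
    effect: float
    seed: int

    @property
    def region_ids(self) -> list[str]:
        return list(self.region_methylation.index)


def _bimodal_baseline(rng: np.random.Generator, n: int,
                      global_mean: float = DEFAULT_GLOBAL_MEAN,
                      concentration: float = 8.0) -> np.ndarray:
    """Bimodal per-region baseline methylation with the requested global mean."""
    w_high = (global_mean - _MU_LOW) / (_MU_HIGH - _MU_LOW)
    high = rng.random(n) < w_high
    mu = np.where(high, _MU_HIGH, _MU_LOW)
    return rng.beta(mu * concentration, (1 - mu) * concentration)


def make_atlas(
    n_tissues: int,
    n_regions: int,
    effect: float,
    seed: int,
    n_specific_per_tissue: int = 20,
    global_mean: float = DEFAULT_GLOBAL_MEAN,
) -> SyntheticAtlasTruth:
    """Tissue atlas with disjoint planted tissue-specific regions.

    Every region starts from a baseline shared across tissues; each tissue
    gets ``n_specific_per_tissue`` disjoint regions shifted by +-``effect``
    (alternating hyper/hypo), with the baseline nudged so the full shift
    always fits inside [0, 1] — so each planted region differs from the
    median of the other tissues by at least ``effect``.
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    if n_regions < n_tissues:
        raise ValueError("need at least as many regions as tissues")
    if not 0 <= effect <= 1:
        raise ValueError("effect must be in [0, 1]")
    if n_specific_per_tissue * n_tissues > n_regions:
        raise ValueError("too many planted regions for n_regions")

    rng = np.random.default_rng(seed)
    tissues = tuple(f"tissue_{i:02d}" for i in range(n_tissues))
    regions = [window_id("chr1", i * 1000, (i + 1) * 1000) for i in range(n_regions)]
    baseline = _bimodal_baseline(rng, n_regions, global_mean)
    M = np.tile(baseline[:, None], (1, n_tissues))

    specific: dict[str, set[str]] = {t: set() for t in tissues}
    if effect > 0 and n_specific_per_tissue > 0:
        # hypermethylated markers are planted in low-baseline regions and
        # hypomethylated ones in high-baseline regions, so the shift fits in
        # [0, 1] without disturbing the shared baseline (or the global mean)
        low_pool = list(np.where(baseline <= 1.0 - effect)[0])
        high_pool = list(np.where(baseline >= effect)[0])
        rng.shuffle(low_pool)
        rng.shuffle(high_pool)
        used: set[int] = set()
        spare = [r for r in rng.permutation(n_regions)]
        for ti, t in enumerate(tissues):
            for j in range(n_specific_per_tissue):
                up = j % 2 == 0
                pool = low_pool if up else high_pool
                while pool and pool[-1] in used:
                    pool.pop()
                if pool:
                    r = pool.pop()
                    used.add(r)
                    M[r, ti] = baseline[r] + (effect if up else -effect)
                else:
                    # no headroom left in the preferred pool: nudge this
                    # region's shared baseline just enough to fit the shift
                    while spare and spare[-1] in used:
                        spare.pop()
                    if not spare:
                        raise ValueError("not enough regions to plant the requested markers")
                    r = spare.pop()
                    used.add(r)
                    base = min(baseline[r], 1.0 - effect) if up else max(baseline[r], effect)
                    M[r, :] = base
                    M[r, ti] = base + (effect if up else -effect)
                specific[t].add(regions[r])
    df = pd.DataFrame(M, index=regions, columns=list(tissues)).clip(0.0, 1.0)
    return SyntheticAtlasTruth(
        tissue_names=tissues, region_methylation=df,
        specific_regions=specific, effect=effect, seed=seed,
    )


def make_atlas_replicates(
    atlas: SyntheticAtlasTruth,
    n_replicates: int = 3,
    concentration: float = 150.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate tissue samples: beta noise around each tissue mean.

    Returns (region x sample matrix, sample -> tissue labels).  Beta
    concentration controls within-tissue replicate spread, mimicking the
    bimodal-but-consistent behaviour of real WGBS replicates.
    """
    rng = np.random.default_rng(seed)
    cols, labels = {}, {}
    mu = atlas.region_methylation.to_numpy().clip(1e-4, 1 - 1e-4)
    for ti, t in enumerate(atlas.tissue_names):
        for r in range(n_replicates):
            name = f"{t}_rep{r}"
            cols[name] = rng.beta(mu[:, ti] * concentration, (1 - mu[:, ti]) * concentration)
            labels[name] = t
    df = pd.DataFrame(cols, index=atlas.region_ids)
    return df, pd.Series(labels)


# ---------------------------------------------------------------- cohort

@dataclass(frozen=True)
class SyntheticCohortTruth:
    """Ground truth for a generated plasma cohort."""

    sample_labels: pd.Series = field(repr=False)          # sample -> group
    true_contributions: pd.DataFrame = field(repr=False)  # sample x tissue, rows sum to 1
    planted_dmrs: dict[tuple[str, str], dict[str, float]] = field(repr=False)
    coverage_model: float
    seed: int


def cohort_annotation(atlas: SyntheticAtlasTruth) -> dict[str, pd.DataFrame]:
    """BED annotations for the synthetic genome: window-to-region mapping is
    1:1 — even-index windows are 'enhancers', odd-index are 'promoters'."""
    rows = []
    for i, rid in enumerate(atlas.region_ids):
        chrom, start, end = rid.rsplit(":", 1)[0], *map(int, rid.rsplit(":", 1)[1].split("-"))
        rows.append((chrom, start, end, "enhancer" if i % 2 == 0 else "promoter"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "feature"])
    return {
        "windows": df[["chrom", "start", "end"]],
        "enhancers": df.loc[df["feature"] == "enhancer", ["chrom", "start", "end"]].reset_index(drop=True),
        "promoters": df.loc[df["feature"] == "promoter", ["chrom", "start", "end"]].reset_index(drop=True),
    }


def make_cohort(
    atlas: SyntheticAtlasTruth,
    group_sizes: dict[str, int],
    dmr_effect: float,
    coverage: float,
    seed: int,
    n_dmrs_per_group: int = 100,
    cpgs_per_window: int = 10,
    dirichlet_concentration: float = 30.0,
    blood_weight: float = 20.0,
    tumor_admixture: dict[str, tuple[str, float]] | None = None,
    biological_sd: float = 0.06,
    noise_free: bool = False,
    control_group: str = "control",
) -> tuple[dict[str, pd.DataFrame], SyntheticCohortTruth]:
    """Per-sample CpG call tables with planted group structure.

    Each sample's expected window methylation is A.x_true for a
    blood-dominant Dirichlet mixture x_true (the first tissue carries
    ``blood_weight`` of the Dirichlet mass, emulating the blood/immune
    dominance of plasma cfDNA); non-control groups get ``n_dmrs_per_group``
    planted DMR shifts of +-``dmr_effect`` — the first non-control group in
    'enhancer' windows, the second in 'promoter' windows — and optional
    tumour-tissue admixture.  Observed counts are binomial draws at Poisson
    coverage per CpG; ``noise_free`` instead emits expectation-preserving
    counts at depth 1e9 per window (levels equal A.x_true to ~1e-9).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= dmr_effect <= 1:
        raise ValueError("dmr_effect must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tissues = list(atlas.tissue_names)
    A = atlas.region_methylation.to_numpy()
    n_regions = A.shape[0]
    ann = cohort_annotation(atlas)
    region_ids = atlas.region_ids

    samples, labels = [], {}
    for g, n in group_sizes.items():
        for i in range(n):
            s = f"{g}_{i:03d}"
            samples.append(s)
            labels[s] = g
    labels = pd.Series(labels)

    alpha = np.ones(len(tissues))
    alpha[0] = blood_weight
    alpha = alpha / alpha.sum() * dirichlet_concentration
    X = rng.dirichlet(alpha, size=len(samples))
    if tumor_admixture:
        for g, (tissue, frac) in tumor_admixture.items():
            ti = tissues.index(tissue)
            rows = [k for k, s in enumerate(samples) if labels[s] == g]
            X[rows] *= (1 - frac)
            X[rows, ti] += frac
    contributions = pd.DataFrame(X, index=samples, columns=tissues)

    # planted DMRs: cancer-like groups get shifts in their regulatory class
    feature_windows = {
        "enhancer": [window_id(*r) for r in ann["enhancers"].itertuples(index=False)],
        "promoter": [window_id(*r) for r in ann["promoters"].itertuples(index=False)],
    }
    noncontrol = [g for g in group_sizes if g != control_group]
    planted: dict[tuple[str, str], dict[str, float]] = {}
    group_shift = {g: {} for g in group_sizes}
    if dmr_effect > 0 and n_dmrs_per_group > 0:
        base_mu = A.mean(axis=1)
        rid_pos = {w: i for i, w in enumerate(region_ids)}
        for gi, g in enumerate(noncontrol):
            klass = "enhancer" if gi % 2 == 0 else "promoter"
            pool = feature_windows[klass]
            # plant hypomethylation in high-baseline windows and vice versa,
            # so the full shift fits in [0, 1] without moving the baseline
            chosen = rng.choice(len(pool), size=min(n_dmrs_per_group, len(pool)), replace=False)
            effects = {}
            for c in chosen:
                wid = pool[c]
                r = rid_pos[wid]
                sign = -1.0 if base_mu[r] > 0.5 else 1.0
                if not 0 <= base_mu[r] + sign * dmr_effect <= 1:
                    sign = -sign
                effects[wid] = sign * dmr_effect
            planted[(control_group, g)] = effects
            group_shift[g] = {rid_pos[w]: e for w, e in effects.items()}

    truth = SyntheticCohortTruth(
        sample_labels=labels,
        true_contributions=contributions,
        planted_dmrs=planted,
        coverage_model=coverage,
        seed=seed,
    )

    calls: dict[str, pd.DataFrame] = {}
    win_coords = [(rid.rsplit(":", 1)[0],) + tuple(map(int, rid.rsplit(":", 1)[1].split("-")))
                  for rid in region_ids]
    for k, s in enumerate(samples):
        mu = A @ X[k]
        for r, e in group_shift[labels[s]].items():
            mu[r] = mu[r] + e
        mu = np.clip(mu, 0.0, 1.0)
        if noise_free:
            depth = 10**9
            n_meth = np.rint(mu * depth).astype(np.int64)
            rows = [(c, st, st + 2, m, depth - m)
                    for (c, st, _), m in zip(win_coords, n_meth)]
            calls[s] = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_meth", "n_unmeth"])
            continue
        # between-patient variation: additive with a floor that does not
        # vanish at extreme methylation, as in real window-level plasma data
        mu_s = np.clip(mu + rng.normal(0.0, biological_sd, size=n_regions),
                       1e-4, 1 - 1e-4)
        depth = rng.poisson(coverage, size=(n_regions, cpgs_per_window))
        meth = rng.binomial(depth, mu_s[:, None])
        rows = []
        for (c, st, _), d_row, m_row in zip(win_coords, depth, meth):
            for j in range(cpgs_per_window):
                if d_row[j] > 0:
                    pos = st + 2 + j * 7
                    rows.append((c, pos, pos + 2, int(m_row[j]), int(d_row[j] - m_row[j])))
        calls[s] = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_meth", "n_unmeth"])
    return calls, truth


# ---------------------------------------------------------------- fragments

@dataclass(frozen=True)
class FragmentModelParams:
    """Mixture model of the cfDNA length distribution.

    Narrow Gaussian at ``main_peak_bp`` (mononucleosome), comb of narrow
    Gaussians at main_peak - k*periodicity (k = 1..6) with geometrically
    decaying weights, a dinucleosomal Gaussian at ``secondary_peak_bp``,
    a short-fragment band and a broad background.  ``group_shift`` moves
    that fraction of mass from the long (secondary) component to the short
    band — the cancer-associated shortening signal.
    """

    main_peak_bp: int = 167
    secondary_peak_bp: int = 320
    periodicity_bp: int = 10
    group_shift: float = 0.0
    n_fragments: int = 100_000
    seed: int = 0
    length_window: tuple[int, int] = (1, 1000)

    def __post_init__(self):
        for peak in (self.main_peak_bp, self.secondary_peak_bp):
            if not 50 <= peak <= 600:
                raise ValueError("peaks must lie in [50, 600]")
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")


def _fragment_pmf(params: FragmentModelParams) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = params.length_window
    x = np.arange(lo, hi + 1, dtype=float)

    def gauss(mu, sd):
        p = np.exp(-0.5 * ((x - mu) / sd) ** 2)
        return p / p.sum()

    w_main, w_comb, w_long, w_short, w_bg = 0.48, 0.18, 0.16, 0.08, 0.10
    s = params.group_shift
    if s < 0 or s > w_long:
        raise ValueError("group_shift must be in [0, long-component weight]")
    w_long -= s
    w_short += s

    pmf = w_main * gauss(params.main_peak_bp, 3.0)
    decay = 0.6 ** np.arange(6)
    comb_w = w_comb * decay / decay.sum()
    for k in range(1, 7):
        pmf += comb_w[k - 1] * gauss(params.main_peak_bp - k * params.periodicity_bp, 1.8)
    pmf += w_long * gauss(params.secondary_peak_bp, 12.0)
    short_band = ((x >= 70) & (x < 150)).astype(float)
    pmf += w_short * short_band / short_band.sum()
    bg = ((x >= 50) & (x <= 600)).astype(float)
    pmf += w_bg * bg / bg.sum()
    return x.astype(np.int64), pmf / pmf.sum()


def make_fragments(params: FragmentModelParams) -> np.ndarray:
    """Sample fragment lengths from the mixture; deterministic given seed."""
    rng = np.random.default_rng(params.seed)
    lengths, pmf = _fragment_pmf(params)
    return rng.choice(lengths, size=params.n_fragments, p=pmf)


# ---------------------------------------------------------------- CNV

def make_cnv_profile(
    segments: list[tuple[str, int, int, float]],
    depth: float,
    seed: int,
    chrom_lengths: dict[str, int] | None = None,
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Per-bin Poisson counts: mean depth x copy_ratio inside planted segments,
    depth elsewhere.  Segments must be non-overlapping with positive ratios."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    for _, _, _, ratio in segments:
        if ratio <= 0:
            raise ValueError("copy_ratio must be positive")
    by_chrom: dict[str, list] = {}
    for chrom, s, e, ratio in segments:
        by_chrom.setdefault(chrom, []).append((s, e, ratio))
    for chrom, segs in by_chrom.items():
        segs.sort()
        for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping segments on {chrom}")
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 30_000_000}
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            ratio = 1.0
            for s, e, r in by_chrom.get(chrom, []):
                ov = min(end, e) - max(start, s)
                if ov > 0:
                    ratio = 1.0 + (r - 1.0) * ov / (end - start)
            rows.append((chrom, start, end, int(rng.poisson(depth * ratio))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    df["mappability"] = 100.0
    df["blacklisted"] = False
    return df


# ---------------------------------------------------------------- spike-in

def make_spikein(
    n_meth_calls: int,
    conv: float,
    n_unmod_calls: int,
    fpr: float,
    seed: int,
    n_positions: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spike-in call tables: binomial converted counts at the stated rates.

    Returns (methylated-control table, unmodified-control table) in the
    bedGraph call format, calls spread over ``n_positions`` CpG sites.
    """
    for rate in (conv, fpr):
        if not 0 <= rate <= 1:
            raise ValueError("rates must be in [0, 1]")
    if n_meth_calls <= 0 or n_unmod_calls <= 0:
        raise ValueError("call counts must be positive")
    rng = np.random.default_rng(seed)

    def table(chrom, n_calls, rate):
        k = min(n_positions, n_calls)
        per = np.full(k, n_calls // k, dtype=np.int64)
        per[: n_calls % k] += 1
        conv_counts = rng.binomial(per, rate)
        rows = [(chrom, 10 + i * 5, 12 + i * 5, int(c), int(t - c))
                for i, (t, c) in enumerate(zip(per, conv_counts))]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_meth", "n_unmeth"])

    return table("lambda_meth", n_meth_calls, conv), table("unmod_2kb", n_unmod_calls, fpr)
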