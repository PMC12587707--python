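"""Per-sample epimutation screening on a cohort β-value matrix.

The screen asks, for every individual and every CpG probe, whether that
individual's β-value is an outlier against the rest of the cohort, then calls
a region when at least ``min_run`` consecutive probes (genomic order, one
chromosome) are significant in the same direction after per-sample FDR
control, and finally interprets each hypermethylated region over a low
background as monoallelic or mosaic methylation from its carrier mean β.

The outlier statistic is the single-case t (Crawford–Howell):

    t = (x − mean_rest) / (sd_rest · sqrt(1 + 1/n_rest)),   df = n_rest − 1

which is algebraically a pooled-variance two-sample t-test with group sizes
1 and n_rest. Two-sided p-values are taken from the t distribution and
adjusted per sample by Benjamini–Hochberg; the discovery threshold is
q < 0.005 with at least 3 consecutive significant CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, IslandSet, ProbeManifest, chrom_sort_key

SD_FLOOR = 1e-6


@dataclass
class ScanParams:
    q_threshold: float = 0.005
    min_run: int = 3
    max_gap: int | None = None  # bp between consecutive probes; None = unlimited
    min_rest_n: int = 10
    # classification bands on carrier mean β (hyper regions over low background)
    low_background_max: float = 0.10
    mosaic_min: float = 0.10
    monoallelic_min: float = 0.25
    monoallelic_max: float = 0.60  # documented band ceiling; not an exclusion cut

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must lie in (0, 1]")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.min_rest_n < 3:
            raise ValueError("min_rest_n must be >= 3")


@dataclass
class OutlierResult:
    sample: str
    probe: str
    beta_self: float
    rest_mean: float
    rest_sd: float
    n_rest: int
    t_stat: float
    df: int
    p: float
    q: float | None = None

    @property
    def direction(self) -> str:
        return "hyper" if self.beta_self > self.rest_mean else "hypo"


@dataclass
class EpimutationRegion:
    sample: str
    chrom: str
    start: int  # 0-based half-open span, bp
    end: int
    probe_ids: list[str]
    mean_beta_carrier: float
    mean_beta_rest: float
    min_q: float
    max_q: float
    direction: str
    islands: list[str] = field(default_factory=list)
    classification: str = ""

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def _loo_stats(values: np.ndarray):
    """Leave-one-out rest mean/sd/count for every cell of a samples × probes array.

    NaN-aware: missing entries contribute to no other sample's statistics and
    receive NaN statistics themselves.
    """
    finite = np.isfinite(values)
    x = np.where(finite, values, 0.0)
    n_tot = finite.sum(axis=0)
    s_tot = x.sum(axis=0)
    ss_tot = (x * x).sum(axis=0)

    n_rest = np.where(finite, n_tot[None, :] - 1, n_tot[None, :])
    s_rest = np.where(finite, s_tot[None, :] - x, s_tot[None, :])
    ss_rest = np.where(finite, ss_tot[None, :] - x * x, ss_tot[None, :])

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rest = s_rest / n_rest
        var_rest = (ss_rest - n_rest * mean_rest**2) / (n_rest - 1)
    var_rest = np.clip(var_rest, 0.0, None)
    sd_rest = np.sqrt(var_rest)
    return mean_rest, sd_rest, n_rest


def single_case_test(beta: BetaMatrix, sample: str, probe: str,
                     min_rest_n: int = 10) -> OutlierResult | None:
    """Test one sample's β at one probe against the rest of the cohort.

    Returns None (an untestable probe) when the sample's value is missing or
    fewer than ``min_rest_n`` rest values are available.
    """
    col = beta.values[probe].to_numpy(dtype=float)
    i = beta.sample_ids.index(sample)
    x = col[i]
    rest = np.delete(col, i)
    rest = rest[np.isfinite(rest)]
    n = rest.size
    if not np.isfinite(x) or n < min_rest_n:
        return None
    mean = float(rest.mean())
    sd = max(float(rest.std(ddof=1)), SD_FLOOR)
    t = (x - mean) / (sd * np.sqrt(1.0 + 1.0 / n))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return OutlierResult(
        sample=sample, probe=probe, beta_self=float(x), rest_mean=mean,
        rest_sd=sd, n_rest=n, t_stat=float(t), df=df, p=p,
    )


def adjust_fdr(p: np.ndarray | list) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaNs propagate untouched."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum() == 0:
        return q
    q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def classify_region(region: EpimutationRegion, params: ScanParams | None = None) -> str:
    """Interpret a region's carrier mean β as monoallelic / mosaic / low-level.

    Only hypermethylated regions over a low background (rest mean below
    ``low_background_max``) are interpretable on this scale; hypomethylated
    regions are labelled as such, and hyper regions over a high background
    fall back to ``low_level``.
    """
    params = params or ScanParams()
    if region.direction == "hypo":
        return "hypomethylated"
    if region.mean_beta_rest >= params.low_background_max:
        return "low_level"
    c = region.mean_beta_carrier
    if c >= params.monoallelic_min:
        return "monoallelic"
    if c >= params.mosaic_min:
        return "mosaic"
    return "low_level"


def call_regions(
    results: list[OutlierResult],
    manifest: ProbeManifest,
    min_run: int = 3,
    q_threshold: float = 0.005,
    max_gap: int | None = None,
) -> list[EpimutationRegion]:
    """Group one sample's per-probe outlier results into maximal runs.

    Probes are walked in genomic order; a run extends while every probe is
    significant (q < threshold), shares the direction and chromosome, and the
    gap to the previous probe does not exceed ``max_gap``. Runs shorter than
    ``min_run`` are discarded. Untestable probes (absent from ``results``)
    break no runs only if they are absent from the manifest too — an NA probe
    present in the manifest is simply skipped, consistent with "consecutive"
    meaning adjacent *testable* probes.
    """
    by_probe = {r.probe: r for r in results}
    missing = set(by_probe) - set(manifest.probe_ids)
    if missing:
        raise KeyError(f"probes absent from manifest: {sorted(missing)[:5]}")
    pos = manifest.positions()

    regions: list[EpimutationRegion] = []
    run: list[OutlierResult] = []
    run_chrom = None
    last_pos = None

    def flush():
        nonlocal run
        if len(run) >= min_run:
            first, last = run[0], run[-1]
            p0 = int(pos.loc[first.probe, "pos"])
            p1 = int(pos.loc[last.probe, "pos"])
            regions.append(
                EpimutationRegion(
                    sample=first.sample,
                    chrom=str(pos.loc[first.probe, "chrom"]),
                    start=p0 - 1,
                    end=p1,
                    probe_ids=[r.probe for r in run],
                    mean_beta_carrier=float(np.mean([r.beta_self for r in run])),
                    mean_beta_rest=float(np.mean([r.rest_mean for r in run])),
                    min_q=float(min(r.q for r in run)),
                    max_q=float(max(r.q for r in run)),
                    direction=first.direction,
                )
            )
        run = []

    for probe in manifest.probe_ids:
        r = by_probe.get(probe)
        if r is None:
            continue  # untestable probe: skipped, does not break the run
        chrom = pos.loc[probe, "chrom"]
        p = int(pos.loc[probe, "pos"])
        significant = r.q is not None and np.isfinite(r.q) and r.q < q_threshold
        if not significant:
            flush()
        else:
            breaks = (
                run
                and (
                    chrom != run_chrom
                    or r.direction != run[-1].direction
                    or (max_gap is not None and p - last_pos > max_gap)
                )
            )
            if breaks:
                flush()
            run.append(r)
            run_chrom = chrom
        last_pos = p
    flush()
    return regions


def annotate_islands(
    regions: list[EpimutationRegion], islands: IslandSet
) -> list[EpimutationRegion]:
    """Attach names of all islands overlapping each region by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for row in islands.intervals.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.name)
    for region in regions:
        tree = trees.get(region.chrom)
        hits = tree.overlap(region.start, region.end) if tree else set()
        region.islands = sorted(iv.data for iv in hits)
    return regions


def _scan_one_sample(
    sample: str,
    i: int,
    values: np.ndarray,
    mean_rest: np.ndarray,
    sd_rest: np.ndarray,
    n_rest: np.ndarray,
    probe_ids: list[str],
    manifest: ProbeManifest,
    params: ScanParams,
) -> list[EpimutationRegion]:
    x = values[i]
    m = mean_rest[i]
    sd = np.maximum(sd_rest[i], SD_FLOOR)
    n = n_rest[i].astype(float)
    testable = np.isfinite(x) & (n >= params.min_rest_n)
    with np.errstate(invalid="ignore"):
        t = (x - m) / (sd * np.sqrt(1.0 + 1.0 / n))
    p = np.full(x.shape, np.nan)
    p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), n[testable] - 1)
    q = adjust_fdr(p)

    # materialize OutlierResults only for significant probes; the indexed
    # region caller uses the testable mask for adjacency between them.
    sig = np.where(testable & np.isfinite(q) & (q < params.q_threshold))[0]
    sig_set = set(int(j) for j in sig)
    sig_results = [
        OutlierResult(
            sample=sample,
            probe=probe_ids[j],
            beta_self=float(x[j]),
            rest_mean=float(m[j]),
            rest_sd=float(sd[j]),
            n_rest=int(n[j]),
            t_stat=float(t[j]),
            df=int(n[j]) - 1,
            p=float(p[j]),
            q=float(q[j]),
        )
        for j in sorted(sig_set)
    ]
    return _call_regions_indexed(
        sig_results, sorted(sig_set), testable, manifest, probe_ids, params
    )


def _call_regions_indexed(
    sig_results: list[OutlierResult],
    sig_idx: list[int],
    testable: np.ndarray,
    manifest: ProbeManifest,
    probe_ids: list[str],
    params: ScanParams,
) -> list[EpimutationRegion]:
    """Region calling when the full per-probe result vector is implicit.

    Two significant probes are consecutive iff no *testable* probe lies
    between them in manifest order, they share chromosome and direction, and
    their genomic gap is within max_gap.
    """
    if not sig_results:
        return []
    pos_tab = manifest.table
    chrom_arr = pos_tab["chrom"].to_numpy()
    pos_arr = pos_tab["pos"].to_numpy()
    # cumulative count of testable probes, to detect intervening testable probes
    cum_testable = np.cumsum(testable.astype(int))

    regions: list[EpimutationRegion] = []
    run: list[tuple[int, OutlierResult]] = []

    def flush():
        nonlocal run
        if len(run) >= params.min_run:
            idxs = [j for j, _ in run]
            rs = [r for _, r in run]
            regions.append(
                EpimutationRegion(
                    sample=rs[0].sample,
                    chrom=str(chrom_arr[idxs[0]]),
                    start=int(pos_arr[idxs[0]]) - 1,
                    end=int(pos_arr[idxs[-1]]),
                    probe_ids=[r.probe for r in rs],
                    mean_beta_carrier=float(np.mean([r.beta_self for r in rs])),
                    mean_beta_rest=float(np.mean([r.rest_mean for r in rs])),
                    min_q=float(min(r.q for r in rs)),
                    max_q=float(max(r.q for r in rs)),
                    direction=rs[0].direction,
                )
            )
        run = []

    for j, r in zip(sig_idx, sig_results):
        if run:
            j_prev, r_prev = run[-1]
            adjacent = cum_testable[j] - cum_testable[j_prev] == 1
            same_chrom = chrom_arr[j] == chrom_arr[j_prev]
            same_dir = r.direction == r_prev.direction
            gap_ok = (
                params.max_gap is None
                or int(pos_arr[j]) - int(pos_arr[j_prev]) <= params.max_gap
            )
            if not (adjacent and same_chrom and same_dir and gap_ok):
                flush()
        run.append((j, r))
    flush()
    return regions


def scan_cohort(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    islands: IslandSet | None = None,
    params: ScanParams | None = None,
) -> list[EpimutationRegion]:
    """Run the per-sample outlier screen over the whole cohort.

    Returns classified, island-annotated regions ordered by
    (sample, chrom, start). Requires at least 12 samples so every
    leave-one-out comparison keeps a usable variance estimate.
    """
    params = params or ScanParams()
    if beta.n_samples < 12:
        raise ValueError("cohort scan needs at least 12 samples")
    # align the matrix to manifest order; every matrix probe must be placed
    manifest_set = set(manifest.probe_ids)
    beta_set = set(beta.probe_ids)
    missing = [p for p in beta.probe_ids if p not in manifest_set]
    if missing:
        raise KeyError(f"probes absent from manifest: {missing[:5]}")
    probe_ids = [p for p in manifest.probe_ids if p in beta_set]
    sub_manifest = ProbeManifest(
        manifest.table[manifest.table["probe_id"].isin(probe_ids)].reset_index(drop=True)
    )
    values = beta.values[probe_ids].to_numpy(dtype=float)
    mean_rest, sd_rest, n_rest = _loo_stats(values)

    regions: list[EpimutationRegion] = []
    order = np.argsort(beta.values.index)  # deterministic under sample permutation
    for i in order:
        sample = beta.sample_ids[i]
        regions.extend(
            _scan_one_sample(
                sample, i, values, mean_rest, sd_rest, n_rest,
                probe_ids, sub_manifest, params,
            )
        )
    for region in regions:
        region.classification = classify_region(region, params)
    if islands is not None:
        annotate_islands(regions, islands)
    regions.sort(key=lambda r: (r.sample, chrom_sort_key(r.chrom), r.start))
    return regions


def regions_to_frame(regions: list[EpimutationRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_probes": r.n_probes,
                "probe_ids": ",".join(r.probe_ids),
                "mean_beta_carrier": r.mean_beta_carrier,
                "mean_beta_rest": r.mean_beta_rest,
                "min_q": r.min_q,
                "max_q": r.max_q,
                "direction": r.direction,
                "islands": ",".join(r.islands),
                "classification": r.classification,
            }
            for r in regions
        ],
        columns=[
            "sample", "chrom", "start", "end", "n_probes", "probe_ids",
            "mean_beta_carrier", "mean_beta_rest", "min_q", "max_q",
            "direction", "islands", "classification",
        ],
    )


def regions_to_bed(regions: list[EpimutationRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end, "name": r.sample}
         for r in regions],
        columns=["chrom", "start", "end", "name"],
    )
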