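"""Synthetic EPIC-like cohorts with known spiked epimutations.

The generator emulates the study design the screen is built for: a blood
methylation-array cohort (default 46 samples) in which at most a handful of
individuals carry an aberrantly methylated region. Probes fall into three
compartments — CpG island (low baseline β), shore (intermediate) and open sea
(high) — laid out in contiguous blocks along synthetic chromosomes, with every
island block registered in a BED-style island set.

Background β for probe *j*, sample *i* is Beta-distributed with the
compartment mean *m* and a shared concentration *s* (α = m·s, β = (1−m)·s),
the standard mean/precision parameterization for methylation fractions. A
spike replaces the carrier's cells in a probe block with draws centred on

    e = (1 − f)·m + f·λ·(0.5 + m/2)

where *f* is the cellular (allelic-carrier) fraction and λ an attenuation
factor modelling the array's compression of a truly hemimethylated signal
(a fully monoallelic island reads ≈0.37, not 0.5, with the default λ=0.7).
f=1 therefore lands in the monoallelic band and small f in the mosaic band.

Expression for a target gene is negatively coupled to mean methylation of a
chosen island region: probe value = a − b·mean(β) + N(0, σ²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    ExpressionMatrix,
    IslandSet,
    ProbeManifest,
    VariantRecord,
)

PROBE_CLASSES = ("island", "shore", "open_sea")


@dataclass
class SpikeSpec:
    """One spiked epimutation: a carrier sample and a probe block.

    ``island_index`` selects which island block receives the spike; ``f`` is
    the fraction of cells carrying the methylated allele and ``lam`` the array
    attenuation. ``n_probes`` limits the spike to the first probes of the
    block (None = whole block).
    """

    carrier: int = 0  # sample index
    island_index: int = 0
    f: float = 1.0
    lam: float = 0.7
    n_probes: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValueError("allelic fraction f must lie in (0, 1]")
        if not 0 < self.lam <= 1:
            raise ValueError("attenuation lambda must lie in (0, 1]")


@dataclass
class SimulationConfig:
    n_samples: int = 46
    n_probes: int = 10_000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"island": 0.20, "shore": 0.30, "open_sea": 0.50}
    )
    class_means: dict[str, float] = field(
        default_factory=lambda: {"island": 0.05, "shore": 0.30, "open_sea": 0.85}
    )
    concentration: float = 150.0
    island_block_size: int = 5
    block_size: int = 10  # probes per shore/open-sea block
    n_chromosomes: int = 4
    probe_spacing: int = 100  # bp between adjacent probes in a block
    block_gap: int = 2_000  # bp between blocks
    spikes: list[SpikeSpec] = field(default_factory=lambda: [SpikeSpec()])
    expression_n_probes: int = 4
    expression_baseline: float = 8.0
    expression_slope: float = 4.0
    expression_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if set(self.class_proportions) != set(PROBE_CLASSES):
            raise ValueError(f"class proportions must cover {PROBE_CLASSES}")


@dataclass
class TruthRecord:
    carrier: str
    probe_ids: list[str]
    expected_beta: float
    label: str  # monoallelic | mosaic
    island_name: str


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "carrier": r.carrier,
                    "probe_ids": ",".join(r.probe_ids),
                    "expected_beta": r.expected_beta,
                    "label": r.label,
                    "island_name": r.island_name,
                }
                for r in self.records
            ],
            columns=["carrier", "probe_ids", "expected_beta", "label", "island_name"],
        )


def expected_spike_beta(m: float, f: float, lam: float) -> float:
    """Expected β of a spiked cell over background mean m."""
    return (1.0 - f) * m + f * lam * (0.5 + m / 2.0)


def _beta_draw(rng: np.random.Generator, mean, conc: float, size=None):
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=size)


def _layout_probes(cfg: SimulationConfig, rng: np.random.Generator):
    """Assign probes to compartment blocks along synthetic chromosomes.

    Returns (manifest DataFrame, island intervals DataFrame, per-probe class
    array, list of island probe-id blocks).
    """
    n_island_blocks = max(
        1, round(cfg.n_probes * cfg.class_proportions["island"] / cfg.island_block_size)
    )
    classes: list[str] = []
    block_of: list[int] = []  # island block index or -1
    island_blocks: list[list[int]] = []
    # interleave island blocks among shore/open-sea blocks deterministically
    remaining = cfg.n_probes
    weights = np.array(
        [cfg.class_proportions["shore"], cfg.class_proportions["open_sea"]]
    )
    weights = weights / weights.sum()
    islands_placed = 0
    while remaining > 0:
        if islands_placed < n_island_blocks:
            k = min(cfg.island_block_size, remaining)
            island_blocks.append(list(range(len(classes), len(classes) + k)))
            classes.extend(["island"] * k)
            block_of.extend([islands_placed] * k)
            islands_placed += 1
            remaining -= k
        if remaining <= 0:
            break
        cls = "shore" if rng.random() < weights[0] else "open_sea"
        k = min(cfg.block_size, remaining)
        classes.extend([cls] * k)
        block_of.extend([-1] * k)
        remaining -= k

    n = len(classes)
    per_chrom = int(np.ceil(n / cfg.n_chromosomes))
    chroms, positions = [], []
    pos = 1_000
    chrom_i = 1
    count_on_chrom = 0
    prev_block = None
    for idx in range(n):
        if count_on_chrom >= per_chrom:
            chrom_i += 1
            count_on_chrom = 0
            pos = 1_000
            prev_block = None
        block_key = (classes[idx], block_of[idx], idx // cfg.block_size)
        if prev_block is not None and block_key != prev_block:
            pos += cfg.block_gap
        chroms.append(f"chr{chrom_i}")
        positions.append(pos)
        pos += cfg.probe_spacing
        prev_block = block_key
        count_on_chrom += 1

    probe_ids = [f"cg{idx:07d}" for idx in range(n)]
    manifest = pd.DataFrame({"probe_id": probe_ids, "chrom": chroms, "pos": positions})

    island_rows = []
    kept_blocks = []
    for bi, block in enumerate(island_blocks):
        block_chroms = {chroms[i] for i in block}
        if len(block_chroms) > 1:  # split across a chromosome boundary: trim
            first_chrom = chroms[block[0]]
            block = [i for i in block if chroms[i] == first_chrom]
        start = positions[block[0]] - 1  # 1-based probe pos -> 0-based BED
        end = positions[block[-1]] + 1
        island_rows.append(
            {"chrom": chroms[block[0]], "start": start, "end": end, "name": f"CGI{bi:04d}"}
        )
        kept_blocks.append([probe_ids[i] for i in block])
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end", "name"])
    return manifest, islands, np.array(classes), kept_blocks


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, ProbeManifest, IslandSet, TruthTable]:
    """Generate a cohort β matrix, its manifest/island annotation and the truth."""
    rng = np.random.default_rng(cfg.seed)
    manifest_df, island_df, classes, island_blocks = _layout_probes(cfg, rng)
    n = len(manifest_df)
    means = np.array([cfg.class_means[c] for c in classes])

    beta = _beta_draw(rng, means[None, :], cfg.concentration, size=(cfg.n_samples, n))
    sample_ids = [f"P-{i + 1:02d}" for i in range(cfg.n_samples)]
    probe_ids = list(manifest_df["probe_id"])
    col_of = {p: j for j, p in enumerate(probe_ids)}

    truth: list[TruthRecord] = []
    for spike in cfg.spikes:
        if spike.carrier >= cfg.n_samples:
            raise ValueError("spike carrier index out of range")
        if spike.island_index >= len(island_blocks):
            raise ValueError("spike island index out of range")
        block = island_blocks[spike.island_index]
        if spike.n_probes is not None:
            block = block[: spike.n_probes]
        chroms = {
            manifest_df.loc[manifest_df["probe_id"] == p, "chrom"].iat[0] for p in block
        }
        if len(chroms) > 1:
            raise ValueError("spike block spans two chromosomes")
        cols = [col_of[p] for p in block]
        m = means[cols]
        e = expected_spike_beta(m, spike.f, spike.lam)
        beta[spike.carrier, cols] = _beta_draw(rng, e, cfg.concentration)
        e_mean = float(np.mean(e))
        label = "monoallelic" if e_mean >= 0.25 else "mosaic"
        truth.append(
            TruthRecord(
                carrier=sample_ids[spike.carrier],
                probe_ids=list(block),
                expected_beta=e_mean,
                label=label,
                island_name=island_df["name"].iat[spike.island_index],
            )
        )

    bm = BetaMatrix(pd.DataFrame(beta, index=sample_ids, columns=probe_ids))
    return bm, ProbeManifest(manifest_df), IslandSet(island_df), TruthTable(truth)


def evaluate_calls(regions, truth: TruthTable, min_overlap: int = 3):
    """Score called regions against the spike truth table.

    A spike counts as recovered when some region called in its carrier shares
    at least ``min_overlap`` probes with the spiked block; every region that
    matches no spike this way is a false positive. Returns
    (n_recovered, n_false_positive).
    """
    recovered = 0
    matched_regions = set()
    for rec in truth.records:
        spike_probes = set(rec.probe_ids)
        hit = False
        for k, region in enumerate(regions):
            if region.sample != rec.carrier:
                continue
            if len(spike_probes & set(region.probe_ids)) >= min_overlap:
                hit = True
                matched_regions.add(k)
        recovered += hit
    n_false = len(regions) - len(matched_regions)
    return recovered, n_false


def simulate_expression(
    beta: BetaMatrix,
    region_probes: list[str],
    cfg: SimulationConfig,
    gene: str = "GENE1",
) -> ExpressionMatrix:
    """Expression probes negatively coupled to mean methylation of a region."""
    if cfg.expression_n_probes < 1:
        raise ValueError("need at least one expression probe")
    missing = [p for p in region_probes if p not in beta.values.columns]
    if missing:
        raise KeyError(f"region probes absent from beta matrix: {missing}")
    rng = np.random.default_rng(cfg.seed + 1)
    mean_beta = beta.values[region_probes].mean(axis=1).to_numpy()
    k = cfg.expression_n_probes
    # distinct per-probe baselines and SD scales so PC1 has a clear top probe
    baselines = cfg.expression_baseline + np.linspace(0, 1, k)
    slope_scale = np.linspace(1.0, 0.6, k)
    vals = (
        baselines[:, None]
        - cfg.expression_slope * slope_scale[:, None] * mean_beta[None, :]
        + rng.normal(0.0, cfg.expression_sigma, size=(k, beta.n_samples))
    )
    probe_ids = [f"expr_{i + 1:02d}" for i in range(k)]
    df = pd.DataFrame(vals, index=probe_ids, columns=beta.sample_ids)
    return ExpressionMatrix(df, {p: gene for p in probe_ids})


def simulate_variant_table(
    cfg: SimulationConfig | None = None,
    n_records: int = 9,
    gene: str = "LTBP4",
) -> list[VariantRecord]:
    """A deterministic test-bed straddling every rare-variant filter boundary.

    The first six records carry one consequence class each (request exactly 6
    to get one per class); missense REVEL scores bracket the 0.644 damaging
    cutoff (0.64 below, 0.65 above) and control minor-allele frequencies
    bracket the 0.1% rarity cutoff.
    """
    control_an = 1_180_062  # 2 x 590,031 diploid controls
    rare_ac = 1_000  # 0.0847% -> passes the MAF <= 0.1% rule
    common_ac = 2_000  # 0.1695% -> filtered out
    boundary = [
        ("frameshift", None, rare_ac),
        ("stop_gain", None, common_ac),  # LoF but too common: MAF rule wins
        ("canonical_splice", None, rare_ac),
        ("start_loss", None, rare_ac),
        ("missense", 0.65, rare_ac),  # just above the REVEL cutoff
        ("other", None, rare_ac),
    ]
    extra = [
        ("missense", 0.64, rare_ac),  # just below the REVEL cutoff
        ("missense", 0.65, common_ac),  # damaging but too common
        ("missense", None, rare_ac),  # missing score: dropped with warning
    ]
    rows = (boundary + extra)[:n_records]
    records = []
    for i, (cls, revel, ac) in enumerate(rows):
        records.append(
            VariantRecord(
                gene=gene,
                identifier=f"var_{i + 1:02d}",
                consequence_class=cls,
                revel=revel,
                control_ac=ac,
                control_an=control_an,
                case_carriers=1,
            )
        )
    return records
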