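"""Seeded synthetic multigenerational methylomes.

The generator emulates the statistical structure the pipeline assumes: a
small genome with TE-dense (including pericentromeric) blocks of high
methylation in all three sequence contexts, gene models with CDS/intron/UTR
structure, and a designated set of epigenetically *labile* regions placed
within or proximal to TEs. Salt-treated P0 samples shift non-CG (CHG/CHH)
methylation at labile regions by ``p0_nonCG_gain`` (a fraction
``hyper_fraction`` of regions gain, the rest lose); their unstressed P1 and
P2 descendants retain ``p1_retention`` and ``p2_retention`` of the shift.
CG sites additionally flip state stochastically at ``cg_epimutation_rate``
per generation in all lineages, and every read is subject to a bisulfite
non-conversion (false methylation) rate estimated downstream from an
unmethylated chloroplast chromosome emitted alongside the genome.

Read depth per site is negative binomial around ``coverage_mean``
(dispersion 0.3 by default); methylated counts are binomial in the
error-perturbed true frequency. CG sites are emitted on both strands
(symmetric dyad frequencies), CHG/CHH on one strand. Identical
configurations (including seed) give byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import contains_points, merge_intervals
from .io import SampleMeta, VALID_GENERATIONS, VALID_LINEAGES, VALID_TREATMENTS

TE_SUPERFAMILY_FREQS = {
    "Helitron": 0.40,
    "MuDR": 0.15,
    "Gypsy": 0.15,
    "Copia": 0.10,
    "HAT": 0.08,
    "LINE/L1": 0.07,
    "SINE": 0.05,
}

_GEN_STEPS = {"G1": 1, "G3": 3, "G5": 5}
_LIN_STEPS = {"P0": 0, "P1": 1, "P2": 2}


class PlacementError(RuntimeError):
    """Requested annotation intervals cannot be placed in the genome."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic multigenerational methylome."""

    genome_length: int = 300_000  # bp per chromosome
    n_chromosomes: int = 1
    chloroplast_length: int = 40_000
    cg_density: float = 0.04
    chg_density: float = 0.04
    chh_density: float = 0.10
    n_te: int = 50
    n_genes: int = 25
    n_labile_regions: int = 40
    p0_nonCG_gain: float = 0.4
    p1_retention: float = 0.6
    p2_retention: float = 0.05
    hyper_fraction: float = 0.81
    background_meth: dict = field(
        default_factory=lambda: {
            "methylated": {"CG": 0.85, "CHG": 0.65, "CHH": 0.35},
            "unmethylated": {"CG": 0.02, "CHG": 0.015, "CHH": 0.01},
            "labile": {"CG": 0.05, "CHG": 0.10, "CHH": 0.10},
        }
    )
    coverage_mean: float = 20.0
    coverage_dispersion: float = 0.3
    conversion_error: float = 0.005
    cg_epimutation_rate: float = 1e-4
    te_proximal: bool = True
    labile_te_max_dist: int = 2000
    pericentromere_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cg_density", "chg_density", "chh_density", "p0_nonCG_gain",
            "p1_retention", "p2_retention", "hyper_fraction",
            "conversion_error", "cg_epimutation_rate", "pericentromere_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cg_density + self.chg_density + self.chh_density > 1.0:
            raise ValueError("context densities must sum to <= 1")
        for group in self.background_meth.values():
            for ctx, v in group.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"background_meth[{ctx}]={v} outside [0, 1]")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        d = {c: self.genome_length for c in self.chrom_names()}
        d["ChrC"] = self.chloroplast_length
        return d

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Ground truth of a simulation run, for recovery tests."""

    mr_truth: pd.DataFrame  # truly methylated blocks (same for all samples)
    labile_truth: pd.DataFrame  # interval, direction, per-context effect
    annotation_truth: dict  # {"genes": frame, "tes": frame}
    block_length_quartiles: tuple[float, float, float]  # 25/50/75% of block lengths

    def to_json_obj(self) -> dict:
        return {
            "mr_truth": self.mr_truth.to_dict(orient="records"),
            "labile_truth": self.labile_truth.to_dict(orient="records"),
            "annotation_truth": {
                k: v.to_dict(orient="records") for k, v in self.annotation_truth.items()
            },
            "block_length_quartiles": list(self.block_length_quartiles),
        }


@dataclass
class Annotation:
    genes: pd.DataFrame  # GFF-style feature frame (gene/CDS/intron/UTR rows)
    tes: pd.DataFrame  # BED-style, name = superfamily
    labile: pd.DataFrame
    truth: TruthSet


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *streams]))


def _sample_stream(seed: int, sample_id: str) -> np.random.Generator:
    return _rng(seed, 0xC0, zlib.crc32(sample_id.encode()))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimConfig) -> Annotation:
    """Place TEs (superfamily-labelled), gene models and labile regions.

    Half the TEs (``pericentromere_fraction``) cluster in the central fifth
    of each chromosome, emulating pericentromeric TE density. Labile regions
    are placed within (hypo) or adjacent to (hyper) TEs when
    ``te_proximal``. Raises :class:`PlacementError` when the requested
    intervals cannot be placed.
    """
    rng = _rng(config.seed, 0xA0)
    chroms = config.chrom_names()
    L = config.genome_length
    tes = _place_tes(config, rng, chroms, L)
    genes = _place_genes(config, rng, chroms, L)
    labile = _place_labile(config, rng, tes, L)
    mr_truth = merge_intervals(tes[["chrom", "start", "end"]]) if len(tes) else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    lengths = (mr_truth["end"] - mr_truth["start"]).to_numpy() if len(mr_truth) else np.array([0.0])
    quartiles = tuple(float(q) for q in np.quantile(lengths, [0.25, 0.5, 0.75]))
    truth = TruthSet(
        mr_truth=mr_truth,
        labile_truth=labile.copy(),
        annotation_truth={"genes": genes, "tes": tes},
        block_length_quartiles=quartiles,
    )
    return Annotation(genes=genes, tes=tes, labile=labile, truth=truth)


def _place_tes(config, rng, chroms, L) -> pd.DataFrame:
    if config.n_te == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    fams = list(TE_SUPERFAMILY_FREQS)
    probs = np.array(list(TE_SUPERFAMILY_FREQS.values()))
    probs = probs / probs.sum()
    peri_lo, peri_hi = int(0.40 * L), int(0.60 * L)
    n_peri = int(round(config.n_te * config.pericentromere_fraction))
    rows = []
    for i in range(config.n_te):
        length = int(np.clip(rng.lognormal(np.log(600), 0.6), 150, 4000))
        in_peri = i < n_peri
        lo, hi = (peri_lo, peri_hi) if in_peri else (0, L)
        if hi - lo <= length:
            raise PlacementError(
                f"TE of length {length} does not fit in [{lo}, {hi}) of a "
                f"{L}-bp chromosome"
            )
        start = int(rng.integers(lo, hi - length))
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        fam = fams[int(rng.choice(len(fams), p=probs))]
        rows.append((chrom, start, start + length, fam, 0.0, "+" if rng.random() < 0.5 else "-"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def _place_genes(config, rng, chroms, L) -> pd.DataFrame:
    rows = []
    peri_lo, peri_hi = int(0.40 * L), int(0.60 * L)
    for g in range(config.n_genes):
        n_exons = int(rng.integers(2, 5))
        exon_len = rng.integers(200, 600, size=n_exons)
        intron_len = rng.integers(80, 300, size=n_exons - 1)
        utr5, utr3 = int(rng.integers(80, 250)), int(rng.integers(100, 350))
        body = int(exon_len.sum() + intron_len.sum())
        total = utr5 + body + utr3
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, max(1, L - total)))
            end = start + total
            if end > L:
                continue
            if start < peri_hi and end > peri_lo:  # keep genes in the arms
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place gene of length {total} outside the pericentromere"
            )
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene{g + 1}"
        rows.append((chrom, start, end, name, 0.0, strand, "gene"))
        cursor = start
        rows.append((chrom, cursor, cursor + utr5, name, 0.0, strand, "five_prime_UTR"))
        cursor += utr5
        for e in range(n_exons):
            rows.append((chrom, cursor, cursor + int(exon_len[e]), name, 0.0, strand, "CDS"))
            cursor += int(exon_len[e])
            if e < n_exons - 1:
                rows.append((chrom, cursor, cursor + int(intron_len[e]), name, 0.0, strand, "intron"))
                cursor += int(intron_len[e])
        rows.append((chrom, cursor, cursor + utr3, name, 0.0, strand, "three_prime_UTR"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand", "feature"])
    if df.empty:
        return df
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def _place_labile(config, rng, tes, L) -> pd.DataFrame:
    rows = []
    te_by_chrom = {c: sub for c, sub in tes.groupby("chrom")} if len(tes) else {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    for r in range(config.n_labile_regions):
        direction = "hyper" if rng.random() < config.hyper_fraction else "hypo"
        length = int(rng.integers(300, 500))
        placed = None
        for _ in range(300):
            if config.te_proximal and len(tes):
                te = tes.iloc[int(rng.integers(0, len(tes)))]
                chrom = te["chrom"]
                if direction == "hypo":
                    # inside the TE (a truly methylated block that can lose)
                    if te["end"] - te["start"] <= length + 20:
                        continue
                    start = int(rng.integers(te["start"], te["end"] - length))
                else:
                    # adjacent, within labile_te_max_dist of the TE edge
                    gap = int(rng.integers(0, min(500, config.labile_te_max_dist)))
                    if rng.random() < 0.5:
                        start = int(te["end"]) + gap
                    else:
                        start = int(te["start"]) - gap - length
            else:
                chrom = f"chr{int(rng.integers(0, config.n_chromosomes)) + 1}"
                start = int(rng.integers(0, max(1, L - length)))
            end = start + length
            if start < 0 or end > L:
                continue
            occ = occupied.setdefault(chrom, [])
            if any(start < e and end > s for s, e in occ):
                continue
            if direction == "hyper" and chrom in te_by_chrom:
                sub = te_by_chrom[chrom]
                if ((sub["start"] < end) & (sub["end"] > start)).any():
                    continue  # gains start from a low baseline, outside TE blocks
            occ.append((start, end))
            placed = (chrom, start, end)
            break
        if placed is None:
            raise PlacementError(
                f"could not place labile region {r + 1}/{config.n_labile_regions}"
            )
        sign = 1.0 if direction == "hyper" else -1.0
        rows.append(
            {
                "chrom": placed[0],
                "start": placed[1],
                "end": placed[2],
                "name": direction,
                "direction": direction,
                "effect_CG": 0.0,
                "effect_CHG": sign * config.p0_nonCG_gain,
                "effect_CHH": sign * config.p0_nonCG_gain,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "direction",
                 "effect_CG", "effect_CHG", "effect_CHH"],
    ).sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# cytosine layout (shared across samples)
# ---------------------------------------------------------------------------


def simulate_sites(config: SimConfig) -> pd.DataFrame:
    """Fixed cytosine layout of the genome (and chloroplast), all samples.

    Returns chrom, pos (1-based), strand, context, tri. CG dyads occupy two
    adjacent positions on opposite strands.
    """
    rng = _rng(config.seed, 0xB0)
    frames = []
    for chrom, L in config.chrom_lengths().items():
        n_cg = int(round(L * config.cg_density))
        n_chg = int(round(L * config.chg_density))
        n_chh = int(round(L * config.chh_density))
        n = n_cg + n_chg + n_chh
        pos = rng.choice(L - 1, size=min(n, L - 1), replace=False) + 1  # 1-based
        rng.shuffle(pos)
        cg, chg, chh = pos[:n_cg], pos[n_cg:n_cg + n_chg], pos[n_cg + n_chg:]
        rows = []
        for p in np.sort(cg):
            rows.append((chrom, int(p), "+", "CG", "CGN"))
            rows.append((chrom, int(p) + 1, "-", "CG", "CGN"))
        strands = rng.random(len(chg)) < 0.5
        for p, s in zip(np.sort(chg), strands):
            rows.append((chrom, int(p), "+" if s else "-", "CHG", "CAG"))
        strands = rng.random(len(chh)) < 0.5
        for p, s in zip(np.sort(chh), strands):
            rows.append((chrom, int(p), "+" if s else "-", "CHH", "CTA"))
        frames.append(pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "tri"]))
    df = pd.concat(frames, ignore_index=True)
    df = df.drop_duplicates(subset=["chrom", "pos", "strand"])
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-sample count tables
# ---------------------------------------------------------------------------


def default_design(
    generations: Sequence[str] = VALID_GENERATIONS,
    lineages: Sequence[str] = VALID_LINEAGES,
    treatments: Sequence[str] = VALID_TREATMENTS,
    replicates: int = 2,
) -> list[SampleMeta]:
    """The full study grid: 3 generations x 3 lineages x 3 treatments, in
    duplicate by default (54 samples); restrict the arguments for subsets."""
    metas = []
    for g in generations:
        for l in lineages:
            for t in treatments:
                for r in range(1, replicates + 1):
                    metas.append(
                        SampleMeta(
                            sample_id=f"{g}_{l}_{t}_r{r}",
                            generation=g,
                            lineage=l,
                            treatment=t,
                            replicate=r,
                        )
                    )
    return metas


def _base_frequencies(config: SimConfig, annotation: Annotation, sites: pd.DataFrame) -> np.ndarray:
    """Baseline true methylation frequency per site (no stress, no noise)."""
    bm = config.background_meth
    freq = np.empty(len(sites))
    ctx = sites["context"].to_numpy()
    for c in ("CG", "CHG", "CHH"):
        freq[ctx == c] = bm["unmethylated"][c]
    coord = sites["pos"].to_numpy(np.int64) - 1
    chroms = sites["chrom"].to_numpy()
    blocks = {
        chrom: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for chrom, sub in annotation.truth.mr_truth.groupby("chrom")
    }
    for chrom, (s, e) in blocks.items():
        sel = chroms == chrom
        inside = contains_points(coord[sel], s, e)
        idx = np.flatnonzero(sel)[inside]
        for c in ("CG", "CHG", "CHH"):
            sub = idx[ctx[idx] == c]
            freq[sub] = bm["methylated"][c]
    # hyper labile regions start from a distinct low baseline
    hyper = annotation.labile[annotation.labile["direction"] == "hyper"]
    for chrom, sub in hyper.groupby("chrom"):
        sel = chroms == chrom
        inside = contains_points(
            coord[sel], sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )
        idx = np.flatnonzero(sel)[inside]
        for c in ("CG", "CHG", "CHH"):
            freq[idx[ctx[idx] == c]] = bm["labile"][c]
    freq[chroms == "ChrC"] = 0.0  # chloroplast is unmethylated
    return freq


def _stress_shift(
    config: SimConfig, annotation: Annotation, sites: pd.DataFrame, meta: SampleMeta
) -> np.ndarray:
    shift = np.zeros(len(sites))
    if meta.treatment == "control" or len(annotation.labile) == 0:
        return shift
    retention = {"P0": 1.0, "P1": config.p1_retention, "P2": config.p2_retention}[meta.lineage]
    if retention == 0.0:
        return shift
    coord = sites["pos"].to_numpy(np.int64) - 1
    chroms = sites["chrom"].to_numpy()
    ctx = sites["context"].to_numpy()
    for row in annotation.labile.itertuples(index=False):
        sel = (chroms == row.chrom) & (coord >= row.start) & (coord < row.end)
        for c, eff in (("CHG", row.effect_CHG), ("CHH", row.effect_CHH), ("CG", row.effect_CG)):
            shift[sel & (ctx == c)] = eff * retention
    return shift


def simulate_samples(
    config: SimConfig,
    annotation: Annotation,
    design: Sequence[SampleMeta],
    sites: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-sample cytosine count tables for a design grid (or subset).

    Per-sample randomness is keyed on (config.seed, sample_id) so subsets of
    the design reproduce exactly the same tables. Sites with zero simulated
    coverage in a sample are absent from that sample's table.
    """
    from .io import validate_design

    validate_design(design)
    if sites is None:
        sites = simulate_sites(config)
    base = _base_frequencies(config, annotation, sites)
    ctx = sites["context"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    coord = sites["pos"].to_numpy(np.int64) - 1
    cg_mask = (ctx == "CG") & (chroms != "ChrC")
    # dyad anchor: both strands of a CG dyad share the plus-strand coordinate
    strand = sites["strand"].to_numpy()
    dyad_anchor = coord.copy()
    dyad_anchor[cg_mask & (strand == "-")] -= 1
    bm = config.background_meth
    out: dict[str, pd.DataFrame] = {}
    for meta in design:
        rng = _sample_stream(config.seed, meta.sample_id)
        freq = np.clip(base + _stress_shift(config, annotation, sites, meta), 0.0, 1.0)
        # stochastic CG epimutations accumulate over elapsed generations
        if config.cg_epimutation_rate > 0 and cg_mask.any():
            n_gen = _GEN_STEPS[meta.generation] + _LIN_STEPS[meta.lineage]
            p_flip = 1.0 - (1.0 - config.cg_epimutation_rate) ** n_gen
            anchors = np.unique(dyad_anchor[cg_mask])
            flips = anchors[rng.random(len(anchors)) < p_flip]
            if len(flips):
                hit = cg_mask & np.isin(dyad_anchor, flips)
                was_meth = freq[hit] >= 0.5
                freq[hit] = np.where(
                    was_meth, bm["unmethylated"]["CG"], bm["methylated"]["CG"]
                )
        f_obs = freq + (1.0 - freq) * config.conversion_error
        cov = _nb_coverage(rng, config, len(sites))
        meth = rng.binomial(cov, f_obs)
        keep = cov > 0
        df = pd.DataFrame(
            {
                "chrom": chroms[keep],
                "pos": sites["pos"].to_numpy()[keep],
                "strand": strand[keep],
                "context": ctx[keep],
                "meth": meth[keep].astype(np.int64),
                "total": cov[keep].astype(np.int64),
                "tri": sites["tri"].to_numpy()[keep],
            }
        )
        out[meta.sample_id] = df.reset_index(drop=True)
    return out


def _nb_coverage(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    mu, d = config.coverage_mean, config.coverage_dispersion
    if d <= 0:
        return rng.poisson(mu, size=n)
    r = 1.0 / d
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=n)


def chloroplast_table(table: pd.DataFrame) -> pd.DataFrame:
    """The chloroplast (control chromosome) slice of a sample table."""
    return table[table["chrom"] == "ChrC"].reset_index(drop=True)


def nuclear_table(table: pd.DataFrame) -> pd.DataFrame:
    """A sample table without the chloroplast control chromosome."""
    return table[table["chrom"] != "ChrC"].reset_index(drop=True)
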