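"""Synthetic two-genotype regulatory-genomics study with planted ground truth.

From one seed and one config this module builds a miniature study: a random
genome, regulatory sites of three classes (A-specific, shared, B-specific)
with class-characteristic motifs written into the sequence, accessibility
tracks for both genotypes, ChIP tracks for three factors in both genotypes
with a co-bound subset, gene models placed next to sites, and replicate
expression tables in which genes linked to strong co-bound sites are
differentially expressed. Every planted fact is recorded in a truth table so
downstream stages can be scored without external data.

Class conventions mirror the biology being emulated: condition A plays the
wild type (sites lost in the knockout carry E-box+GATA composites and are
bound by the LMO2/TAL1/LDB1 complex), condition B plays the knockout
(gained sites carry LEF/TCF motifs), and shared sites carry ETS/SP1/CREB
motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import io as rio
from .model import GeneModel, ExpressionRecord, Pwm, Summit, TagTrack

A_SPECIFIC = "A_specific"
SHARED = "shared"
B_SPECIFIC = "B_specific"
FACTORS = ("LMO2", "TAL1", "LDB1")


def default_pwms(pseudo: float = 0.8) -> Dict[str, Pwm]:
    """The PWM fixtures shipped with the package, keyed by name."""
    with resources.as_file(resources.files("regrank.data") / "pwms.txt") as path:
        pwms = rio.read_pwm(path, pseudo=pseudo)
    return {p.name: p for p in pwms}


@dataclass
class StudyConfig:
    """Defaults define the study conditions; change them only to model a
    different study, not to make a particular analysis look better."""

    # genome
    n_chrom: int = 2
    chrom_len: int = 200_000
    gc: float = 0.41
    # sites
    n_a_specific: int = 100
    n_shared: int = 100
    n_b_specific: int = 100
    n_cobound: int = 40
    min_gap: int = 1200
    edge_margin: int = 2000
    composite_gaps: Tuple[int, ...] = (9, 10)
    # tracks
    enrichment: float = 4.0
    site_strength_mean: float = 200.0
    site_strength_sigma: float = 0.5
    decay_halfwidth: int = 150
    noise_rate: float = 0.005
    summit_fp_fraction: float = 0.05
    factor_scales: Dict[str, float] = field(
        default_factory=lambda: {"LMO2": 1.0, "TAL1": 0.7, "LDB1": 0.5}
    )
    # chance of a factor binding outside the forced co-bound subset
    p_factor_a_specific: Dict[str, float] = field(
        default_factory=lambda: {"LMO2": 0.5, "TAL1": 0.2, "LDB1": 0.1}
    )
    p_factor_shared: Dict[str, float] = field(
        default_factory=lambda: {"LMO2": 0.2, "TAL1": 0.15, "LDB1": 0.1}
    )
    # genes / expression
    n_genes: int = 200
    n_short_genes: int = 10
    # offset + length are bounded so a site's own gene (<= 250 bp away) is
    # always strictly nearer than any neighbouring site's gene (>= 350 bp
    # away at the 1200 bp minimum site gap): truth links stay identifiable
    gene_offset: Tuple[int, int] = (100, 250)
    gene_length: Tuple[int, int] = (400, 600)
    p_gene_contains_site: float = 0.3
    effect_log2fc: float = 3.0
    expr_sigma: float = 0.4
    n_replicates: int = 3
    baseline_log2fpkm_mean: float = 4.9
    baseline_log2fpkm_sigma: float = 1.0
    conditions: Tuple[str, str] = ("WT", "KO")
    stages: Tuple[str, ...] = ("HB", "HE1")
    # planted profile matrix for clustering
    profile_groups: int = 3
    profile_genes_per_group: int = 50
    profile_samples: int = 6
    profile_noise: float = 0.15
    profile_amplitude: float = 2.0


@dataclass
class PlantedSite:
    site_id: str
    chrom: str
    pos: int
    class_truth: str
    planted_motifs: List[Tuple[str, int, str]] = field(default_factory=list)
    cobound_factors: frozenset = frozenset()
    strength: float = 0.0
    linked_gene: Optional[str] = None
    planted_log2fc_expression: float = 0.0

    @property
    def is_cobound(self) -> bool:
        return set(FACTORS) <= set(self.cobound_factors)


# ---------------------------------------------------------------------------
# genome


def make_genome(
    seed: int, n_chrom: int = 2, chrom_len: int = 200_000, gc: float = 0.41
) -> Tuple[Dict[str, str], Dict[str, int]]:
    """I.i.d. random genome at the requested GC content, deterministic per seed."""
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    genome = {}
    for i in range(n_chrom):
        seq = rng.choice(bases, size=chrom_len, p=p)
        genome[f"chr{i + 1}"] = "".join(seq)
    return genome, {c: len(s) for c, s in genome.items()}


# ---------------------------------------------------------------------------
# site planting

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _site_positions(config: StudyConfig, rng: np.random.Generator) -> List[Tuple[str, int]]:
    n_total = config.n_a_specific + config.n_shared + config.n_b_specific
    if n_total == 0:
        return []
    per_chrom = int(np.ceil(n_total / config.n_chrom))
    usable = config.chrom_len - 2 * config.edge_margin
    if per_chrom * config.min_gap > usable:
        raise ValueError("requested sites exceed genome capacity at this min_gap")
    spacing = usable / per_chrom
    jitter_max = max(1, int(spacing - config.min_gap))
    positions = []
    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        for k in range(per_chrom):
            if len(positions) >= n_total:
                break
            pos = config.edge_margin + int(k * spacing) + int(rng.integers(0, jitter_max))
            positions.append((chrom, pos))
    return positions


def plant_sites(
    genome: Dict[str, str],
    config: StudyConfig,
    pwms: Dict[str, Pwm],
    seed: int,
) -> Tuple[Dict[str, str], List[PlantedSite]]:
    """Choose site positions, assign classes, and write motif instances.

    A-specific sites get an E-box/GATA composite centred on the summit,
    B-specific sites a LEF/TCF motif, shared sites an ETS motif plus an SP1 or
    CREB motif nearby. Consensus sequences are written on a random strand at
    recorded offsets, so rescanning at the maximum-score threshold must
    recover every planted instance.
    """
    rng = np.random.default_rng(seed)
    positions = _site_positions(config, rng)
    n_total = len(positions)
    if n_total == 0:
        return genome, []
    classes = (
        [A_SPECIFIC] * config.n_a_specific
        + [SHARED] * config.n_shared
        + [B_SPECIFIC] * config.n_b_specific
    )
    rng.shuffle(classes)

    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    sites: List[PlantedSite] = []

    def write_motif(chrom: str, start: int, name: str, strand: str) -> None:
        inst = pwms[name].consensus
        if strand == "-":
            inst = _revcomp(inst)
        seqs[chrom][start : start + len(inst)] = inst.encode("ascii")

    for i, ((chrom, pos), cls) in enumerate(zip(positions, classes)):
        site = PlantedSite(site_id=f"site{i:04d}", chrom=chrom, pos=pos, class_truth=cls)
        if cls == A_SPECIFIC:
            gap = int(rng.choice(config.composite_gaps))
            len1, len2 = len(pwms["EBOX"]), len(pwms["GATA"])
            total = len1 + gap + len2
            start = pos - total // 2
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                write_motif(chrom, start, "EBOX", "+")
                write_motif(chrom, start + len1 + gap, "GATA", "+")
                site.planted_motifs = [("EBOX", start - pos, "+"),
                                       ("GATA", start + len1 + gap - pos, "+")]
            else:
                # reverse-complement the whole cassette: GATA core first
                write_motif(chrom, start, "GATA", "-")
                write_motif(chrom, start + len2 + gap, "EBOX", "-")
                site.planted_motifs = [("GATA", start - pos, "-"),
                                       ("EBOX", start + len2 + gap - pos, "-")]
        elif cls == B_SPECIFIC:
            L = len(pwms["LEF"])
            start = pos - L // 2
            strand = "+" if rng.random() < 0.5 else "-"
            write_motif(chrom, start, "LEF", strand)
            site.planted_motifs = [("LEF", start - pos, strand)]
        else:
            L = len(pwms["ETS"])
            start = pos - L // 2
            strand = "+" if rng.random() < 0.5 else "-"
            write_motif(chrom, start, "ETS", strand)
            site.planted_motifs = [("ETS", start - pos, strand)]
            extra = "SP1" if rng.random() < 0.5 else "CREB"
            off = -30 if extra == "SP1" else 28
            write_motif(chrom, pos + off, extra, "+")
            site.planted_motifs.append((extra, off, "+"))
        sites.append(site)

    mutated = {c: s.decode("ascii") for c, s in seqs.items()}
    return mutated, sites


def assign_factors(sites: List[PlantedSite], config: StudyConfig, seed: int) -> None:
    """Assign ChIP factor membership and latent site strengths in place.

    ``n_cobound`` A-specific sites are forced to carry all three factors;
    elsewhere factors join independently with class-dependent probabilities
    (never at B-specific sites, which lack the complex).
    """
    rng = np.random.default_rng(seed)
    a_idx = [i for i, s in enumerate(sites) if s.class_truth == A_SPECIFIC]
    if config.n_cobound > len(a_idx):
        raise ValueError("n_cobound exceeds the number of A-specific sites")
    forced = set(rng.choice(a_idx, size=config.n_cobound, replace=False).tolist())
    for i, site in enumerate(sites):
        members = set()
        if i in forced:
            members = set(FACTORS)
        elif site.class_truth == A_SPECIFIC:
            probs = config.p_factor_a_specific
            members = {f for f in FACTORS if rng.random() < probs[f]}
        elif site.class_truth == SHARED:
            probs = config.p_factor_shared
            members = {f for f in FACTORS if rng.random() < probs[f]}
        site.cobound_factors = frozenset(members)
        site.strength = float(
            config.site_strength_mean
            * np.exp(rng.normal(0.0, config.site_strength_sigma)
                     - config.site_strength_sigma ** 2 / 2)
        )


# ---------------------------------------------------------------------------
# tracks


def _triangular_kernel(halfwidth: int) -> np.ndarray:
    d = np.arange(-halfwidth + 1, halfwidth)
    return (1.0 - np.abs(d) / halfwidth) / halfwidth


def simulate_tracks(
    sites: Sequence[PlantedSite],
    chrom_sizes: Dict[str, int],
    config: StudyConfig,
    seed: int,
) -> Tuple[Dict[str, TagTrack], Dict[str, List[Summit]]]:
    """Poisson tag tracks plus emitted summit lists for every assay.

    Track keys: ``acc_A``, ``acc_B`` (accessibility per genotype) and
    ``chip_<FACTOR>_<GENOTYPE>``. Signal is a triangular kernel (apex at the
    summit) whose integral is the site strength, scaled per track; A-specific
    sites keep ``1/enrichment`` of their mass in the B track and vice versa,
    so the expected A/B window ratio at specific sites equals ``enrichment``.
    Background is uniform Poisson at ``noise_rate`` per base. Summit lists are
    the planted positions of sites called in that track plus a
    ``summit_fp_fraction`` of uniformly placed false positives.
    """
    if config.enrichment <= 1:
        raise ValueError("enrichment must be > 1")
    rng = np.random.default_rng(seed)
    h = config.decay_halfwidth
    kernel = _triangular_kernel(h)

    def site_mass(site: PlantedSite, track: str) -> float:
        cls = site.class_truth
        if track == "acc_A":
            return site.strength * (1.0 if cls in (A_SPECIFIC, SHARED) else 1.0 / config.enrichment)
        if track == "acc_B":
            return site.strength * (1.0 if cls in (B_SPECIFIC, SHARED) else 1.0 / config.enrichment)
        _, factor, genotype = track.split("_")
        if factor not in site.cobound_factors:
            return 0.0
        scale = config.factor_scales[factor]
        if genotype == "A":
            return site.strength * scale
        # genotype B (knockout of the complex's bridge): LMO2 gone everywhere,
        # partner binding persists only where the site itself survives
        if factor == "LMO2" or cls == A_SPECIFIC:
            return 0.0
        return site.strength * scale

    track_names = ["acc_A", "acc_B"] + [
        f"chip_{f}_{g}" for f in FACTORS for g in ("A", "B")
    ]
    tracks: Dict[str, TagTrack] = {}
    summits: Dict[str, List[Summit]] = {}
    chroms = list(chrom_sizes)
    for name in track_names:
        lam = {c: np.full(n, config.noise_rate) for c, n in chrom_sizes.items()}
        called: List[Summit] = []
        condition = name.split("_")[-1]
        factor = name.split("_")[1] if name.startswith("chip") else "DHS"
        for site in sites:
            mass = site_mass(site, name)
            if mass <= 0:
                continue
            vec = lam[site.chrom]
            lo = site.pos - h + 1
            hi = site.pos + h
            klo, khi = max(0, lo), min(len(vec), hi)
            vec[klo:khi] += mass * kernel[klo - lo : khi - lo]
            # accessibility summits are "called" only where the site carries
            # full (not residual 1/enrichment) mass; any ChIP mass is a peak
            if name.startswith("chip") or mass > site.strength / config.enrichment:
                called.append(Summit(site.chrom, site.pos, condition, factor))
        n_fp = int(round(config.summit_fp_fraction * len(called)))
        for _ in range(n_fp):
            c = chroms[int(rng.integers(0, len(chroms)))]
            p = int(rng.integers(config.edge_margin, chrom_sizes[c] - config.edge_margin))
            called.append(Summit(c, p, condition, factor))
        called.sort(key=lambda s: (s.chrom, s.pos))
        counts = {c: rng.poisson(v).astype(np.int64) for c, v in lam.items()}
        tracks[name] = TagTrack(counts)
        summits[name] = called
    return tracks, summits


# ---------------------------------------------------------------------------
# genes and expression


def place_genes(
    sites: Sequence[PlantedSite],
    chrom_sizes: Dict[str, int],
    config: StudyConfig,
    seed: int,
) -> List[GeneModel]:
    """Place one gene next to (or over) a subset of sites; link co-bound sites.

    Every truth co-bound site gets a gene first (these become the
    differentially expressed targets), then remaining genes go to a random
    subset of the other sites. A few deliberately short genes exercise the
    transcript-length filter downstream.
    """
    rng = np.random.default_rng(seed)
    cobound = [s for s in sites if s.is_cobound]
    others = [s for s in sites if not s.is_cobound]
    n_other = max(0, config.n_genes - len(cobound))
    chosen_others = list(
        rng.choice(len(others), size=min(n_other, len(others)), replace=False)
    )
    hosts = cobound + [others[i] for i in chosen_others]
    genes: List[GeneModel] = []
    for gi, site in enumerate(hosts):
        gene_id = f"gene{gi:04d}"
        length = int(rng.integers(*config.gene_length))
        if gi >= len(hosts) - config.n_short_genes:
            length = int(rng.integers(80, 160))  # below the 200 bp filter
        if rng.random() < config.p_gene_contains_site and length > 300:
            start = site.pos - int(rng.integers(100, min(length - 100, 250)))
        else:
            start = site.pos + int(rng.integers(*config.gene_offset))
        start = max(0, min(start, chrom_sizes[site.chrom] - length - 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id, site.chrom, start, start + length, strand))
        site.linked_gene = gene_id
    return genes


def simulate_expression(
    sites: Sequence[PlantedSite],
    genes: Sequence[GeneModel],
    config: StudyConfig,
    seed: int,
) -> Dict[str, List[ExpressionRecord]]:
    """Replicate FPKM tables per stage with planted differential expression.

    Genes linked to truth co-bound sites receive a planted log2 difference
    (condition A higher) at the late stage, proportional to the site's ChIP
    strength; all other genes share a null log-normal distribution. P-values
    come from a two-sample t-test on the simulated replicate triplets.
    """
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in genes}
    site_by_gene = {s.linked_gene: s for s in sites if s.linked_gene is not None}
    max_strength = max((s.strength for s in sites if s.is_cobound), default=1.0)
    for s in sites:
        if s.is_cobound and s.linked_gene is not None:
            s.planted_log2fc_expression = config.effect_log2fc * s.strength / max_strength

    cond_a, cond_b = config.conditions
    tables: Dict[str, List[ExpressionRecord]] = {}
    base = {
        g.gene_id: rng.normal(config.baseline_log2fpkm_mean, config.baseline_log2fpkm_sigma)
        for g in genes
    }
    late_stage = config.stages[-1]
    for stage in config.stages:
        records = []
        for g in genes:
            site = site_by_gene.get(g.gene_id)
            fc = site.planted_log2fc_expression if (site is not None and stage == late_stage) else 0.0
            mu_a = base[g.gene_id] + fc / 2
            mu_b = base[g.gene_id] - fc / 2
            reps_a = rng.normal(mu_a, config.expr_sigma, size=config.n_replicates)
            reps_b = rng.normal(mu_b, config.expr_sigma, size=config.n_replicates)
            p = float(stats.ttest_ind(reps_a, reps_b).pvalue)
            if np.isnan(p):
                p = 1.0
            fpkm = {}
            for r, v in enumerate(reps_a, start=1):
                fpkm[f"{cond_a}_rep{r}"] = float(2.0 ** v)
            for r, v in enumerate(reps_b, start=1):
                fpkm[f"{cond_b}_rep{r}"] = float(2.0 ** v)
            records.append(
                ExpressionRecord(g.gene_id, fpkm, p, g.end - g.start)
            )
        tables[stage] = records
    return tables


def make_profile_matrix(
    n_per_group: int = 50,
    n_samples: int = 6,
    k: int = 3,
    noise: float = 0.15,
    amplitude: float = 2.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Planted k-group expression-profile matrix for clustering tests.

    Each group follows one block profile (high in its own third of the
    samples) plus Gaussian noise; returns (matrix, group labels 0..k-1).
    """
    rng = np.random.default_rng(seed)
    block = max(1, n_samples // k)
    rows, labels = [], []
    for g in range(k):
        profile = np.zeros(n_samples)
        profile[g * block : (g + 1) * block] = amplitude
        for _ in range(n_per_group):
            rows.append(profile + rng.normal(0.0, noise, size=n_samples))
            labels.append(g)
    return np.array(rows), np.array(labels)


# ---------------------------------------------------------------------------
# the full study


@dataclass
class StudyData:
    config: StudyConfig
    seed: int
    genome: Dict[str, str]
    chrom_sizes: Dict[str, int]
    sites: List[PlantedSite]
    tracks: Dict[str, TagTrack]
    summits: Dict[str, List[Summit]]
    genes: List[GeneModel]
    expression: Dict[str, List[ExpressionRecord]]
    profile_matrix: np.ndarray
    profile_labels: np.ndarray
    pwms: Dict[str, Pwm]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "site_id": s.site_id,
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "class_truth": s.class_truth,
                    "planted_motifs": ";".join(
                        f"{n}:{off}:{strand}" for n, off, strand in s.planted_motifs
                    ),
                    "cobound_factors": "+".join(sorted(s.cobound_factors)),
                    "strength": s.strength,
                    "linked_gene": s.linked_gene or "",
                    "planted_log2fc_expression": s.planted_log2fc_expression,
                }
            )
        return pd.DataFrame(rows)


def generate_study(seed: int, config: Optional[StudyConfig] = None) -> StudyData:
    """Build the complete miniature study, deterministic per seed."""
    config = config or StudyConfig()
    ss = np.random.SeedSequence(seed)
    s_genome, s_plant, s_factor, s_tracks, s_genes, s_expr, s_prof = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(7)
    ]
    pwms = default_pwms()
    genome, chrom_sizes = make_genome(
        s_genome, config.n_chrom, config.chrom_len, config.gc
    )
    genome, sites = plant_sites(genome, config, pwms, s_plant)
    assign_factors(sites, config, s_factor)
    tracks, summits = simulate_tracks(sites, chrom_sizes, config, s_tracks)
    genes = place_genes(sites, chrom_sizes, config, s_genes)
    expression = simulate_expression(sites, genes, config, s_expr)
    profile, labels = make_profile_matrix(
        config.profile_genes_per_group,
        config.profile_samples,
        config.profile_groups,
        config.profile_noise,
        config.profile_amplitude,
        s_prof,
    )
    return StudyData(
        config=config,
        seed=seed,
        genome=genome,
        chrom_sizes=chrom_sizes,
        sites=sites,
        tracks=tracks,
        summits=summits,
        genes=genes,
        expression=expression,
        profile_matrix=profile,
        profile_labels=labels,
        pwms=pwms,
    )


def write_study(data: StudyData, outdir) -> None:
    """Emit every study artefact as plain-text files under ``outdir``."""
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_fasta(data.genome, out / "genome.fa")
    rio.write_chrom_sizes(data.chrom_sizes, out / "chrom.sizes")
    for name, track in data.tracks.items():
        rio.write_bedgraph(track, out / f"{name}.bedgraph")
    for name, summits in data.summits.items():
        rio.write_summits(summits, out / f"{name}.summits.bed")
    rio.write_gene_models(data.genes, out / "genes.tsv")
    for stage, records in data.expression.items():
        rio.write_expression_table(records, out / f"expression_{stage}.tsv")
    data.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    np.savetxt(out / "profile_matrix.tsv", data.profile_matrix, delimiter="\t")
    np.savetxt(out / "profile_labels.tsv", data.profile_labels, fmt="%d")
    cfg = asdict(data.config)
    cfg["seed"] = data.seed
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
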