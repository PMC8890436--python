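"""Synthetic genomes and RNA-seq experiments with planted latent splicing.

The generator builds a toy multi-exon coding annotation in which candidate
donors of all three classes (LSS, adSS_3n, adSS_fs) are planted at known
coordinates with controlled donor-model scores, then simulates a 2-case /
2-control split-read experiment: canonical junction counts are negative
binomial (the standard overdispersed bulk-RNA-seq model), latent junction
counts are Poisson around canonical x usage, and usage is multiplied by an
effect fold in case samples for the activated subset of planted sites.
Exon-extension coverage is per-nucleotide Poisson noise around the latent
counts.  Everything is deterministic given (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import STOP_CODONS, reverse_complement
from .junctions import CoverageProfile, JunctionCounts
from .scoring import DonorSiteModel, fit_maxent, score_kmer

BASES = "ACGT"

#: positional base frequencies of a donor 9-mer (3 exonic + GT + 4 intronic),
#: shaped after the canonical CAG|GTAAGT consensus
DONOR_CONSENSUS_FREQS = np.array(
    [
        [0.35, 0.35, 0.20, 0.10],  # -3 (A/C rich)
        [0.60, 0.10, 0.10, 0.20],  # -2 A
        [0.10, 0.05, 0.80, 0.05],  # -1 G
        [0.00, 0.00, 1.00, 0.00],  # +1 G
        [0.00, 0.00, 0.00, 1.00],  # +2 T
        [0.60, 0.05, 0.25, 0.10],  # +3 A/G
        [0.70, 0.05, 0.10, 0.15],  # +4 A
        [0.10, 0.05, 0.75, 0.10],  # +5 G
        [0.15, 0.15, 0.20, 0.50],  # +6 T
    ]
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedClassSpec:
    """How many sites of one class to plant, and with what properties."""

    count: int
    n_activated: int
    score_range: tuple[float, float] = (1.0, 12.0)
    extension_range: tuple[int, int] = (30, 90)

    def __post_init__(self) -> None:
        if self.n_activated > self.count:
            raise SimulationError("cannot activate more sites than are planted")
        if self.extension_range[0] < 12:
            raise SimulationError("planted extensions must be at least 12 nt")


@dataclass(frozen=True)
class SimulationParams:
    n_genes: int = 8
    exons_per_gene: tuple[int, int] = (3, 4)
    exon_codons: tuple[int, int] = (40, 60)
    intron_length: tuple[int, int] = (150, 300)
    planted: dict = field(
        default_factory=lambda: {
            "LSS": PlantedClassSpec(count=6, n_activated=3),
            "adSS_3n": PlantedClassSpec(count=4, n_activated=2),
            "adSS_fs": PlantedClassSpec(count=4, n_activated=2),
        }
    )
    canonical_mean: float = 500.0
    canonical_dispersion: float = 0.1
    baseline_usage: float = 0.01
    effect_fold: float = 5.0
    replicate_jitter_sigma: float = 0.1
    background_mapped_reads: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_usage < 1:
            raise SimulationError("baseline_usage must lie in [0, 1)")
        if self.effect_fold < 1:
            raise SimulationError("effect_fold must be >= 1")
        if self.canonical_mean <= 0 or self.n_genes <= 0:
            raise SimulationError("counts and means must be positive")
        for cls, spec in self.planted.items():
            if cls == "adSS_3n" and spec.extension_range[1] - spec.extension_range[0] < 3:
                raise SimulationError("adSS_3n extension range must contain a multiple of 3")


@dataclass
class PlantedSite:
    site_id: str
    site_class: str
    chrom: str
    strand: str
    gt_start: int
    parent_donor: int
    gene_id: str
    extension_length: int
    activated: bool
    effect_fold: float
    # genomic 0-based half-open coordinates
    latent_junction: tuple[int, int]
    canonical_junction: tuple[int, int]
    extension_interval: tuple[int, int]

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.gt_start, self.parent_donor)


@dataclass
class SimulatedReference:
    chrom: str
    sequence: str
    gtf_lines: list[str]
    introns: list[dict]  # canonical junction records, one per intron
    planted: list[PlantedSite]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": p.site_id,
                    "site_class": p.site_class,
                    "chrom": p.chrom,
                    "strand": p.strand,
                    "gt_start": p.gt_start,
                    "parent5ss": p.parent_donor,
                    "gene": p.gene_id,
                    "extension_len": p.extension_length,
                    "activated": p.activated,
                    "effect_fold": p.effect_fold,
                }
                for p in self.planted
            ]
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "ref.fa", "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.sequence), 60):
                fh.write(self.sequence[i : i + 60] + "\n")
        with open(outdir / "genes.gtf", "w") as fh:
            fh.writelines(line + "\n" for line in self.gtf_lines)
        self.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)


def sample_consensus_donors(rng: np.random.Generator, n: int) -> list[str]:
    """Draw donor 9-mers from the consensus positional frequencies."""
    out = []
    for _ in range(n):
        out.append("".join(rng.choice(list(BASES), p=row) for row in DONOR_CONSENSUS_FREQS))
    return out


def default_donor_model(seed: int = 0, n_training: int = 500, kind: str = "maxent") -> DonorSiteModel:
    """Donor model fitted to consensus-sampled training 9-mers."""
    rng = np.random.default_rng(seed)
    training = sample_consensus_donors(rng, n_training)
    if kind == "maxent":
        return fit_maxent(training)
    from .scoring import fit_pwm

    return fit_pwm(training, pseudocount=0.5)


def _sample_scored_donor(
    rng: np.random.Generator,
    model: DonorSiteModel,
    score_range: tuple[float, float],
    max_attempts: int = 10_000,
) -> str:
    """Rejection-sample a consensus donor 9-mer whose score lands in range."""
    lo, hi = score_range
    for _ in range(max_attempts):
        w = "".join(rng.choice(list(BASES), p=row) for row in DONOR_CONSENSUS_FREQS)
        if lo <= score_kmer(model, w) <= hi:
            return w
    raise SimulationError(f"could not sample a donor 9-mer with score in [{lo}, {hi}]")


_NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [ _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), size=n) ]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _build_extension(
    rng: np.random.Generator,
    d: int,
    site_class: str,
    donor_tail: str,
    candidate_head: str,
    max_attempts: int = 1000,
) -> str:
    """Sense extension sequence of length d, respecting class constraints.

    The first 6 bases are the annotated donor's intronic 6-mer, the last 3
    the candidate donor's exonic 3-mer.  Reading frame continues from the
    upstream exon with offset 0, so in-frame codons start at multiples of 3.
    """
    assert d >= 12 and len(donor_tail) == 6 and len(candidate_head) == 3
    for _ in range(max_attempts):
        middle = _random_seq(rng, d - 9)
        ext = donor_tail + middle + candidate_head
        if site_class == "LSS":
            # plant one in-frame STOP strictly inside the free middle region
            slots = [i for i in range(0, d - 2, 3) if i >= 6 and i + 3 <= d - 3]
            if not slots:
                continue
            pos = int(rng.choice(slots))
            stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
            ext = ext[:pos] + stop + ext[pos + 3 :]
        has_stop = any(ext[i : i + 3] in STOP_CODONS for i in range(0, d - 2, 3))
        if site_class == "LSS" and has_stop:
            return ext
        if site_class != "LSS" and not has_stop:
            return ext
    raise SimulationError(f"could not build a {site_class} extension of length {d}")


def _choose_extension_length(rng: np.random.Generator, spec: PlantedClassSpec, site_class: str, max_d: int) -> int:
    lo = max(spec.extension_range[0], 12)
    hi = min(spec.extension_range[1], max_d)
    if hi < lo:
        raise SimulationError("intron too short for the requested extension range")
    for _ in range(1000):
        d = int(rng.integers(lo, hi + 1))
        if site_class == "adSS_3n" and d % 3 != 0:
            continue
        if site_class == "adSS_fs" and d % 3 == 0:
            continue
        return d
    raise SimulationError("no feasible extension length in range")


def generate_reference(
    params: SimulationParams,
    model: DonorSiteModel,
    seed: int | None = None,
    chrom: str = "chrS",
) -> SimulatedReference:
    """Build a toy genome + GTF with planted candidate donors of all classes.

    Genes alternate between strands and are laid out on one chromosome with
    spacer sequence between them.  Every exon is fully coding with a length
    divisible by 3, so the reading frame offset at each donor is 0.  At most
    one site is planted per intron.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    want = [
        (cls, spec, idx)
        for cls, spec in sorted(params.planted.items())
        for idx in range(spec.count)
    ]
    n_introns_total = 0
    gene_plan = []
    for g in range(params.n_genes):
        n_exons = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
        gene_plan.append(n_exons)
        n_introns_total += n_exons - 1
    if len(want) > n_introns_total:
        raise SimulationError(
            f"{len(want)} planted sites requested but only {n_introns_total} introns available"
        )
    # assign planted sites to distinct introns
    intron_slots = list(rng.permutation(n_introns_total))[: len(want)]
    plant_by_intron = {slot: want[i] for i, slot in enumerate(intron_slots)}
    activated_ids: dict[str, set[int]] = {}
    for cls, spec in params.planted.items():
        activated_ids[cls] = set(rng.choice(spec.count, size=spec.n_activated, replace=False).tolist())

    genome_parts: list[str] = []
    gtf_lines: list[str] = []
    introns: list[dict] = []
    planted: list[PlantedSite] = []
    offset = 0
    intron_counter = 0
    spacer = 300

    for g, n_exons in enumerate(gene_plan):
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"gene{g + 1}"
        tx_id = f"tx{g + 1}"
        # ---- design the gene in sense space
        sense_parts: list[str] = []
        exon_ivs: list[tuple[int, int]] = []  # sense coords
        intron_records: list[dict] = []  # sense coords + payload
        pos = 0
        for e in range(n_exons):
            n_codons = int(rng.integers(params.exon_codons[0], params.exon_codons[1] + 1))
            codons = _random_codons(rng, n_codons)
            if e == 0:
                codons[0] = "ATG"
            if e == n_exons - 1:
                codons[-1] = "TAA"
            exon_seq = "".join(codons)
            if e < n_exons - 1:
                # carve the intron following this exon
                intron_len = int(rng.integers(params.intron_length[0], params.intron_length[1] + 1))
                donor_9mer = _sample_scored_donor(rng, model, (0.0, math.inf))
                exon_seq = exon_seq[:-3] + _nonstop_or_resample(rng, donor_9mer[:3])
                sense_parts.append(exon_seq)
                exon_ivs.append((pos, pos + len(exon_seq)))
                pos += len(exon_seq)
                intron_seq, payload = _design_intron(
                    rng, params, model, intron_len, donor_9mer, plant_by_intron.get(intron_counter)
                )
                intron_records.append({"start": pos, "end": pos + intron_len, "payload": payload})
                sense_parts.append(intron_seq)
                pos += intron_len
                intron_counter += 1
            else:
                sense_parts.append(exon_seq)
                exon_ivs.append((pos, pos + len(exon_seq)))
                pos += len(exon_seq)
        sense_seq = "".join(sense_parts)
        gene_len = len(sense_seq)

        # ---- place on the genome
        genome_parts.append(_random_seq(rng, spacer))
        gene_offset = offset + spacer
        genome_parts.append(sense_seq if strand == "+" else reverse_complement(sense_seq))
        offset = gene_offset + gene_len

        def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
            s, e = iv
            if strand == "+":
                return (gene_offset + s, gene_offset + e)
            return (gene_offset + gene_len - e, gene_offset + gene_len - s)

        for iv in exon_ivs:
            gs, ge = to_genomic(iv)
            for feat in ("exon", "CDS"):
                gtf_lines.append(
                    f"{chrom}\tlatsplice_sim\t{feat}\t{gs + 1}\t{ge}\t.\t{strand}\t0\t"
                    f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
                )
        for local_idx, rec in enumerate(intron_records):
            gs, ge = to_genomic((rec["start"], rec["end"]))
            donor_gt = gs if strand == "+" else ge - 2
            intron_info = {
                "chrom": chrom,
                "strand": strand,
                "gene": gene_id,
                "donor_gt": donor_gt,
                "canonical_junction": (gs, ge),
            }
            introns.append(intron_info)
            payload = rec["payload"]
            if payload is not None:
                cls, spec, idx, d = payload
                if strand == "+":
                    gt_start = gs + d
                    latent = (gt_start, ge)
                    ext_iv = (gs, gt_start)
                else:
                    gt_start = ge - d - 2
                    latent = (gs, gt_start + 2)
                    ext_iv = (gt_start + 2, ge)
                planted.append(
                    PlantedSite(
                        site_id=f"{cls}_{idx + 1}",
                        site_class=cls,
                        chrom=chrom,
                        strand=strand,
                        gt_start=gt_start,
                        parent_donor=donor_gt,
                        gene_id=gene_id,
                        extension_length=d,
                        activated=idx in activated_ids[cls],
                        effect_fold=params.effect_fold,
                        latent_junction=latent,
                        canonical_junction=(gs, ge),
                        extension_interval=ext_iv,
                    )
                )
    genome_parts.append(_random_seq(rng, spacer))
    sequence = "".join(genome_parts)
    gtf_lines.sort(key=lambda l: (int(l.split("\t")[3]), l.split("\t")[2]))
    return SimulatedReference(
        chrom=chrom, sequence=sequence, gtf_lines=gtf_lines, introns=introns, planted=planted
    )


def _nonstop_or_resample(rng: np.random.Generator, head: str) -> str:
    """Exon-final codon taken from a donor window; STOPs would truncate the CDS."""
    if head not in STOP_CODONS:
        return head
    return _NONSTOP_CODONS[int(rng.integers(0, len(_NONSTOP_CODONS)))]


def _design_intron(rng, params, model, intron_len, donor_9mer, plant):
    """Sense-space intron sequence; returns (seq, payload or None)."""
    acceptor = "TTTTTTCTCAG"
    if plant is None:
        body = _random_seq(rng, intron_len - 6 - len(acceptor))
        # donor_9mer[3:5] is the fixed GT; [5:9] the remaining intronic bases
        return "GT" + donor_9mer[5:9] + body + acceptor, None
    cls, spec, idx = plant
    max_d = intron_len - 20 - 6  # residual intron >= 20 incl. the candidate window
    d = _choose_extension_length(rng, spec, cls, max_d)
    if cls != "LSS":
        # the donor tail contributes the in-frame codon at extension offset 3,
        # and the candidate head the one ending at d when d % 3 == 0; neither
        # may be a STOP for a no-PTC class
        while donor_9mer[6:9] in STOP_CODONS:
            donor_9mer = donor_9mer[:6] + _sample_scored_donor(rng, model, (0.0, math.inf))[6:9]
    candidate_9mer = _sample_scored_donor(rng, model, spec.score_range)
    if cls != "LSS" and d % 3 == 0:
        while candidate_9mer[:3] in STOP_CODONS:
            candidate_9mer = _sample_scored_donor(rng, model, spec.score_range)
    ext = _build_extension(rng, d, cls, "GT" + donor_9mer[5:9], candidate_9mer[:3])
    rest_len = intron_len - d - 6 - len(acceptor)
    rest = _random_seq(rng, rest_len)
    seq = ext + "GT" + candidate_9mer[5:9] + rest + acceptor
    assert len(seq) == intron_len
    return seq, (cls, spec, idx, d)


# ---------------------------------------------------------------------------
# experiment simulation


@dataclass
class SimulatedExperiment:
    counts: list[JunctionCounts]
    profiles: dict[tuple, CoverageProfile]
    bedgraphs: dict[str, pd.DataFrame]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, jc in enumerate(self.counts, start=1):
            jc.to_tsv(outdir / f"j{i}.tsv")
        for i, (sample, bg) in enumerate(self.bedgraphs.items(), start=1):
            bg.to_csv(outdir / f"cov{i}.bedgraph", sep="\t", header=False, index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture (mean/dispersion form)."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=size)
    return rng.poisson(lam)


def simulate_experiment(
    reference: SimulatedReference,
    params: SimulationParams,
    seed: int | None = None,
) -> SimulatedExperiment:
    """Simulate 2 case + 2 control samples of split-read counts and coverage.

    Canonical counts per intron are negative binomial; latent counts per
    planted site are Poisson around canonical x usage, where usage is the
    baseline fraction times per-replicate lognormal jitter, multiplied by
    the effect fold in case samples for activated sites.  Extension coverage
    is per-nucleotide Poisson noise around the latent count, and each
    profile is normalized by the sample's canonical split-read support.
    """
    rng = np.random.default_rng((params.seed if seed is None else seed) + 1)
    samples = [
        ("case_1", "case", 1),
        ("case_2", "case", 2),
        ("control_1", "control", 1),
        ("control_2", "control", 2),
    ]
    counts_by_sample: dict[str, JunctionCounts] = {
        sid: JunctionCounts(sample_id=sid, condition=cond, replicate=rep)
        for sid, cond, rep in samples
    }
    profiles: dict[tuple, CoverageProfile] = {}
    bedgraph_rows: dict[str, list] = {sid: [] for sid, _, _ in samples}

    planted_by_intron = {p.canonical_junction: p for p in reference.planted}
    for intron in reference.introns:
        canon_key = (intron["chrom"], *intron["canonical_junction"])
        canon = _nb_counts(rng, params.canonical_mean, params.canonical_dispersion, len(samples))
        site = planted_by_intron.get(intron["canonical_junction"])
        for (sid, cond, rep), c in zip(samples, canon):
            jc = counts_by_sample[sid]
            jc.counts[canon_key] = int(c)
            if site is None:
                continue
            usage = params.baseline_usage * float(
                rng.lognormal(mean=0.0, sigma=params.replicate_jitter_sigma)
            )
            if site.activated and cond == "case":
                usage *= site.effect_fold
            latent = int(rng.poisson(c * usage))
            latent_key = (site.chrom, *site.latent_junction)
            if latent > 0:
                jc.counts[latent_key] = latent
            # per-nucleotide extension coverage with Poisson noise around the
            # latent junction support
            s, e = site.extension_interval
            depths = rng.poisson(latent, size=e - s).astype(float) if latent > 0 else np.zeros(e - s)
            run_start = 0
            for i in range(1, e - s + 1):
                if i == e - s or depths[i] != depths[run_start]:
                    if depths[run_start] > 0:
                        bedgraph_rows[sid].append(
                            (site.chrom, s + run_start, s + i, float(depths[run_start]))
                        )
                    run_start = i
            profiles[(site.key, sid)] = CoverageProfile(
                site_key=site.key, sample_id=sid, depths=depths, normalization=float(c)
            )
    counts = []
    for sid, _, _ in samples:
        jc = counts_by_sample[sid]
        jc.total_mapped_reads = params.background_mapped_reads + sum(jc.counts.values())
        counts.append(jc)
    bedgraphs = {
        sid: pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"]).sort_values(
            ["chrom", "start"]
        ).reset_index(drop=True)
        for sid, rows in bedgraph_rows.items()
    }
    return SimulatedExperiment(
        counts=counts, profiles=profiles, bedgraphs=bedgraphs, truth=reference.truth_table()
    )


def write_sam(counts: JunctionCounts, chrom_lengths: dict[str, int], path: str | Path, read_len: int = 50) -> None:
    """Emit a SAM whose N-gapped reads reproduce the junction counts exactly.

    Each junction observation becomes one read with CIGAR
    ``{read_len}M{gap}N{read_len}M`` anchored ``read_len`` bases before the
    gap; the remaining ``total_mapped_reads`` are padded with ungapped reads.
    """
    n_junction_reads = sum(counts.counts.values())
    n_filler = counts.total_mapped_reads - n_junction_reads
    if n_filler < 0:
        raise SimulationError("total_mapped_reads smaller than junction read total")
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        i = 0
        for (chrom, gap_start, gap_end), n in sorted(counts.counts.items()):
            gap = gap_end - gap_start
            pos = gap_start - read_len + 1  # 1-based leftmost
            if pos < 1:
                raise SimulationError(f"junction at {chrom}:{gap_start} too close to the chromosome start")
            cigar = f"{read_len}M{gap}N{read_len}M"
            seq = "A" * (2 * read_len)
            for _ in range(n):
                i += 1
                fh.write(f"r{i}\t0\t{chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n")
        first_chrom = next(iter(chrom_lengths))
        for _ in range(n_filler):
            i += 1
            fh.write(f"r{i}\t0\t{first_chrom}\t1\t60\t{read_len}M\t*\t0\t0\t{'A' * read_len}\t*\n")
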