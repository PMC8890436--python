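"""Genome-wide catalog of latent and alternative 5' splice sites.

Within-CDS introns of multi-exon coding transcripts are scanned for GT
dinucleotides that could act as alternative donors.  A candidate GT would
extend the upstream exon by up to 1000 nt while leaving at least 20 nt of
residual intron, and must not coincide with an annotated donor.  Each
candidate is scored with a donor model and classified by what its use would
do to the reading frame of the extended exon:

* ``LSS`` — at least one in-frame STOP codon in the extension (a premature
  termination codon, PTC, enters the mRNA directly);
* ``adSS_3n`` — no in-frame STOP and extension length divisible by 3 (the
  frame and protein remain intact apart from inserted residues);
* ``adSS_fs`` — no in-frame STOP but a length not divisible by 3, shifting
  the downstream frame and creating a PTC indirectly.

Coordinates are 0-based half-open internally; GTF input is 1-based
inclusive; BED-like output is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .scoring import DONOR_EXONIC, DONOR_INTRONIC, DonorSiteModel, ScoreThreshold, score_kmer

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
MAX_EXTENSION = 1000
MIN_RESIDUAL_INTRON = 20

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    pass


@dataclass
class Transcript:
    """One transcript with exon and CDS structure in genomic coordinates.

    ``exons`` and ``cds`` are 0-based half-open intervals sorted in genomic
    order; transcript (5'->3') order is the reverse of genomic order on the
    minus strand.
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def exons_in_sense(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_in_sense(self) -> list[tuple[int, int]]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))


@dataclass
class GenomeAnnotation:
    transcripts: list[Transcript]
    annotated_donors: set[tuple[str, str, int]]  # (chrom, strand, GT genomic start)

    def __post_init__(self) -> None:
        self.by_gene: dict[str, list[Transcript]] = {}
        for tx in self.transcripts:
            self.by_gene.setdefault(tx.gene_id, []).append(tx)


@dataclass
class CandidateSite:
    """One intronic GT candidate attached to its parent annotated donor."""

    chrom: str
    strand: str
    gt_start: int  # genomic start of the GT dinucleotide, 0-based
    parent_donor: int  # genomic GT start of the annotated 5'SS
    extension_length: int
    residual_intron: int
    gene_id: str
    transcript_ids: list[str] = field(default_factory=list)
    site_class: str = "unclassified"
    has_inframe_stop: bool = False
    score: float = float("nan")
    parent_score: float = float("nan")
    reject_reason: str = ""
    # 0-based half-open genomic interval of the exon extension
    extension_interval: tuple[int, int] = (0, 0)
    # junction keys (chrom-less): (gap_start, gap_end)
    latent_junction: tuple[int, int] = (0, 0)
    canonical_junction: tuple[int, int] = (0, 0)

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.gt_start, self.parent_donor)


@dataclass
class SiteCatalog:
    sites: list[CandidateSite]

    def __post_init__(self) -> None:
        keys = [s.key for s in self.sites]
        if len(keys) != len(set(keys)):
            raise AnnotationError("duplicate candidate keys in catalog")
        self.by_donor: dict[tuple[str, str, int], list[CandidateSite]] = {}
        self.by_gene: dict[str, list[CandidateSite]] = {}
        for s in self.sites:
            self.by_donor.setdefault((s.chrom, s.strand, s.parent_donor), []).append(s)
            self.by_gene.setdefault(s.gene_id, []).append(s)

    def of_class(self, site_class: str) -> "SiteCatalog":
        return SiteCatalog([s for s in self.sites if s.site_class == site_class])

    def __len__(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": s.chrom,
                "start": s.gt_start,
                "end": s.gt_start + 2,
                "name": f"{s.gene_id}:{s.parent_donor}:{s.gt_start}",
                "score": s.score,
                "strand": s.strand,
                "site_class": s.site_class,
                "extension_len": s.extension_length,
                "residual_intron": s.residual_intron,
                "has_stop": int(s.has_inframe_stop),
                "gene": s.gene_id,
                "parent5ss": s.parent_donor,
                "parent_score": s.parent_score,
                "transcripts": ",".join(s.transcript_ids),
            }
            for s in self.sites
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "name", "score", "strand", "site_class",
                "extension_len", "residual_intron", "has_stop", "gene",
                "parent5ss", "parent_score", "transcripts",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SiteCatalog":
        df = pd.read_csv(path, sep="\t")
        sites = []
        for row in df.itertuples(index=False):
            site = CandidateSite(
                chrom=str(row.chrom),
                strand=row.strand,
                gt_start=int(row.start),
                parent_donor=int(row.parent5ss),
                extension_length=int(row.extension_len),
                residual_intron=int(row.residual_intron),
                gene_id=str(row.gene),
                transcript_ids=str(row.transcripts).split(","),
                site_class=row.site_class,
                has_inframe_stop=bool(row.has_stop),
                score=float(row.score),
                parent_score=float(row.parent_score),
            )
            _set_junctions(site)
            sites.append(site)
        return cls(sites)


def _set_junctions(site: CandidateSite) -> None:
    """Derive extension interval and junction gap coordinates from the site."""
    d, r = site.extension_length, site.residual_intron
    if site.strand == "+":
        intron_start = site.gt_start - d
        intron_end = site.gt_start + r
        site.extension_interval = (intron_start, site.gt_start)
        site.latent_junction = (site.gt_start, intron_end)
    else:
        intron_end = site.gt_start + 2 + d
        intron_start = site.gt_start + 2 - r
        site.extension_interval = (site.gt_start + 2, intron_end)
        site.latent_junction = (intron_start, site.gt_start + 2)
    site.canonical_junction = (intron_start, intron_end)


# ---------------------------------------------------------------------------
# annotation reading


def _parse_transcripts(gtf_path: str | Path) -> list[Transcript]:
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, Transcript] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tx_id = feat.attributes["transcript_id"][0]
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{gtf_path}: {feat.featuretype} feature at {feat.seqid}:{feat.start} "
                f"missing {exc} attribute"
            ) from exc
        tx = exons.setdefault(
            tx_id,
            Transcript(id=tx_id, gene_id=gene_id, chrom=feat.seqid, strand=feat.strand, exons=[], cds=[]),
        )
        interval = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        (tx.exons if feat.featuretype == "exon" else tx.cds).append(interval)
    for tx in exons.values():
        tx.exons.sort()
        tx.cds.sort()
    return list(exons.values())


def _donors_of(tx: Transcript) -> list[tuple[str, str, int]]:
    """Annotated donor GT starts: the first two intronic bases of each intron."""
    donors = []
    exons = tx.exons
    for (_, e1), (s2, _) in zip(exons, exons[1:]):
        if tx.strand == "+":
            donors.append((tx.chrom, "+", e1))
        else:
            donors.append((tx.chrom, "-", s2 - 2))
    return donors


def read_annotation(gtf_paths: Sequence[str | Path], genome: Mapping | None = None) -> GenomeAnnotation:
    """Load one or more GTFs into a GenomeAnnotation.

    Multi-exon coding transcripts (>=2 exons, with CDS) are retained for
    candidate generation; the annotated-donor set is the union over all
    inputs and all transcripts, including those excluded from scanning.
    Transcripts whose CDS falls outside their exons are skipped with a
    warning.
    """
    if isinstance(gtf_paths, (str, Path)):
        gtf_paths = [gtf_paths]
    transcripts: list[Transcript] = []
    donors: set[tuple[str, str, int]] = set()
    for path in gtf_paths:
        for tx in _parse_transcripts(path):
            donors.update(_donors_of(tx))
            if len(tx.exons) < 2 or not tx.cds:
                continue
            contained = all(
                any(es <= cs and ce <= ee for es, ee in tx.exons) for cs, ce in tx.cds
            )
            if not contained:
                log.warning("transcript %s: CDS not contained in exons; skipped", tx.id)
                continue
            transcripts.append(tx)
    return GenomeAnnotation(transcripts=transcripts, annotated_donors=donors)


# ---------------------------------------------------------------------------
# candidate enumeration and classification


def _fetch(genome: Mapping, chrom: str, start: int, end: int) -> str:
    """0-based half-open slice of a chromosome from a pyfaidx-like mapping."""
    if chrom not in genome:
        raise AnnotationError(f"chromosome {chrom!r} absent from the genome FASTA")
    return str(genome[chrom][start:end]).upper()


def _frame_offset_at_exon_end(tx: Transcript, exon_index_sense: int) -> int | None:
    """Bases of the current codon already emitted at the end of sense exon i.

    Returns None when the exon carries no CDS (no frame to continue).
    """
    cds_sense = tx.cds_in_sense()
    exons_sense = tx.exons_in_sense()
    exon = exons_sense[exon_index_sense]
    total = 0
    seen = False
    for iv in cds_sense:
        s, e = iv
        if exon[0] <= s and e <= exon[1]:
            seen = True
        # count CDS bases at or upstream (in sense) of this exon's end
        if tx.strand == "+":
            if e <= exon[1]:
                total += e - s
        else:
            if s >= exon[0]:
                total += e - s
    if not seen:
        return None
    return total % 3


def _sense_interval_seq(genome: Mapping, chrom: str, strand: str, start: int, end: int) -> str:
    seq = _fetch(genome, chrom, start, end)
    return seq if strand == "+" else reverse_complement(seq)


def enumerate_candidates(
    annotation: GenomeAnnotation,
    genome: Mapping,
    max_extension: int = MAX_EXTENSION,
    min_residual: int = MIN_RESIDUAL_INTRON,
) -> list[CandidateSite]:
    """Emit every unclassified GT candidate in within-CDS introns.

    A within-CDS intron separates two consecutive exons that both carry CDS.
    Candidates are deduplicated by (chrom, strand, GT start, parent donor)
    across transcripts; transcript ids accumulate on the shared record.
    """
    found: dict[tuple, CandidateSite] = {}
    for tx in annotation.transcripts:
        exons_sense = tx.exons_in_sense()
        cds_sense = tx.cds_in_sense()

        def exon_has_cds(exon: tuple[int, int]) -> bool:
            return any(exon[0] <= s and e <= exon[1] for s, e in cds_sense)

        for i, (up, down) in enumerate(zip(exons_sense, exons_sense[1:])):
            if not (exon_has_cds(up) and exon_has_cds(down)):
                continue
            if tx.strand == "+":
                intron = (up[1], down[0])
            else:
                intron = (down[1], up[0])
            intron_len = intron[1] - intron[0]
            if intron_len < min_residual + 2:
                continue
            sense_seq = _sense_interval_seq(genome, tx.chrom, tx.strand, *intron)
            donor_key = (tx.chrom, tx.strand, intron[0] if tx.strand == "+" else intron[1] - 2)
            hi = min(max_extension, intron_len - min_residual)
            for d in range(1, hi + 1):
                if sense_seq[d : d + 2] != "GT":
                    continue
                if tx.strand == "+":
                    gt_start = intron[0] + d
                else:
                    gt_start = intron[1] - d - 2
                if (tx.chrom, tx.strand, gt_start) in annotation.annotated_donors:
                    continue
                key = (tx.chrom, tx.strand, gt_start, donor_key[2])
                site = found.get(key)
                if site is None:
                    site = CandidateSite(
                        chrom=tx.chrom,
                        strand=tx.strand,
                        gt_start=gt_start,
                        parent_donor=donor_key[2],
                        extension_length=d,
                        residual_intron=intron_len - d,
                        gene_id=tx.gene_id,
                    )
                    _set_junctions(site)
                    found[key] = site
                if tx.id not in site.transcript_ids:
                    site.transcript_ids.append(tx.id)
    return list(found.values())


def find_inframe_stop(extension_seq: str, frame_offset: int, exon_tail: str = "") -> bool:
    """True if translating through the extension hits a STOP codon.

    ``frame_offset`` is the number of bases of the current codon already
    emitted by the upstream exon; ``exon_tail`` supplies those bases so the
    junction-spanning codon can be tested.  A STOP counts when at least one
    of its bases lies in the extension and the codon ends within it
    (a codon that would run past the candidate GT does not count).
    """
    need = (3 - frame_offset) % 3
    if frame_offset and len(exon_tail) < frame_offset:
        raise AnnotationError("exon_tail shorter than frame_offset")
    if need and need <= len(extension_seq):
        codon = exon_tail[len(exon_tail) - frame_offset :] + extension_seq[:need]
        if codon in STOP_CODONS:
            return True
    for start in range(need, len(extension_seq) - 2, 3):
        if extension_seq[start : start + 3] in STOP_CODONS:
            return True
    return False


def classify_candidate(
    site: CandidateSite,
    genome: Mapping,
    frame_offset: int,
) -> str:
    """Assign LSS / adSS_3n / adSS_fs based on the in-frame STOP criterion."""
    ext_seq = _sense_interval_seq(genome, site.chrom, site.strand, *site.extension_interval)
    if "N" in ext_seq:
        site.site_class = "rejected"
        site.reject_reason = "ambiguous_bases"
        return site.site_class
    if frame_offset:
        s, e = site.extension_interval
        if site.strand == "+":
            tail = _sense_interval_seq(genome, site.chrom, "+", s - frame_offset, s)
        else:
            tail = _sense_interval_seq(genome, site.chrom, "-", e, e + frame_offset)
    else:
        tail = ""
    if "N" in tail:
        site.site_class = "rejected"
        site.reject_reason = "ambiguous_bases"
        return site.site_class
    site.has_inframe_stop = find_inframe_stop(ext_seq, frame_offset, tail)
    if site.has_inframe_stop:
        site.site_class = "LSS"
    elif site.extension_length % 3 == 0:
        site.site_class = "adSS_3n"
    else:
        site.site_class = "adSS_fs"
    return site.site_class


def donor_window(genome: Mapping, chrom: str, strand: str, gt_start: int,
                 exonic: int = DONOR_EXONIC, intronic: int = DONOR_INTRONIC) -> str:
    """Sense-strand 9-mer around a donor GT: `exonic` upstream bases + GT + rest."""
    if strand == "+":
        return _sense_interval_seq(genome, chrom, "+", gt_start - exonic, gt_start + intronic)
    return _sense_interval_seq(genome, chrom, "-", gt_start + 2 - intronic, gt_start + 2 + exonic)


def _frame_for_site(site: CandidateSite, annotation: GenomeAnnotation) -> int | None:
    """Frame offset at the parent exon end, from the longest-CDS transcript."""
    best: tuple[int, int] | None = None  # (cds_length, frame)
    frames = set()
    for tx_id in site.transcript_ids:
        tx = next(t for t in annotation.by_gene[site.gene_id] if t.id == tx_id)
        exons_sense = tx.exons_in_sense()
        for i, exon in enumerate(exons_sense[:-1]):
            donor = (exon[1] if tx.strand == "+" else exon[0] - 2)
            if donor == site.parent_donor:
                f = _frame_offset_at_exon_end(tx, i)
                if f is None:
                    continue
                frames.add(f)
                if best is None or tx.cds_length > best[0]:
                    best = (tx.cds_length, f)
    if best is None:
        return None
    if len(frames) > 1:
        log.info("site %s: transcripts disagree on frame %s; using longest CDS", site.key, frames)
    return best[1]


def build_catalog(
    annotation: GenomeAnnotation,
    genome: Mapping,
    model: DonorSiteModel,
    threshold: ScoreThreshold = ScoreThreshold(0.0, inclusive=True),
    max_extension: int = MAX_EXTENSION,
    min_residual: int = MIN_RESIDUAL_INTRON,
) -> SiteCatalog:
    """Enumerate, score, threshold-filter, and classify all candidates."""
    candidates = enumerate_candidates(annotation, genome, max_extension, min_residual)
    kept: list[CandidateSite] = []
    parent_scores: dict[tuple[str, str, int], float] = {}
    for site in candidates:
        window = donor_window(genome, site.chrom, site.strand, site.gt_start)
        if "N" in window or len(window) != model.k:
            continue
        site.score = score_kmer(model, window)
        if not threshold.passes(site.score):
            continue
        frame = _frame_for_site(site, annotation)
        if frame is None:
            continue
        classify_candidate(site, genome, frame)
        if site.site_class == "rejected":
            continue
        pkey = (site.chrom, site.strand, site.parent_donor)
        if pkey not in parent_scores:
            pwindow = donor_window(genome, *pkey)
            parent_scores[pkey] = (
                score_kmer(model, pwindow) if len(pwindow) == model.k and "N" not in pwindow else float("nan")
            )
        site.parent_score = parent_scores[pkey]
        kept.append(site)
    return SiteCatalog(kept)


# ---------------------------------------------------------------------------
# summaries


def summarize_catalog(catalog: SiteCatalog) -> dict[str, pd.DataFrame]:
    """Per-donor and per-gene summary tables of the LSS landscape.

    Returns a dict with:
      per_donor — strongest/closest LSS per annotated donor, score difference
        (donor score − strongest LSS score), and whether a stronger LSS exists;
      extension_lengths — extension lengths labelled single/closest/strongest;
      per_gene — LSS counts per gene (strand-agnostic);
      fractions — single-row table incl. fraction of donors with a stronger LSS.
    """
    if not catalog.sites:
        raise AnnotationError("cannot summarize an empty catalog")
    lss = [s for s in catalog.sites if s.site_class == "LSS"]
    per_donor_rows = []
    length_rows = []
    groups: dict[tuple, list[CandidateSite]] = {}
    for s in lss:
        groups.setdefault((s.chrom, s.strand, s.parent_donor), []).append(s)
    for (chrom, strand, donor), sites in groups.items():
        strongest = max(sites, key=lambda s: s.score)
        closest = min(sites, key=lambda s: s.extension_length)
        donor_score = strongest.parent_score
        per_donor_rows.append(
            {
                "chrom": chrom,
                "strand": strand,
                "donor": donor,
                "n_lss": len(sites),
                "strongest_score": strongest.score,
                "strongest_extension": strongest.extension_length,
                "closest_extension": closest.extension_length,
                "donor_score": donor_score,
                "score_difference": donor_score - strongest.score,
                "stronger_lss_exists": bool(strongest.score > donor_score),
            }
        )
        if len(sites) == 1:
            length_rows.append({"kind": "single", "extension_len": sites[0].extension_length})
        length_rows.append({"kind": "closest", "extension_len": closest.extension_length})
        length_rows.append({"kind": "strongest", "extension_len": strongest.extension_length})
    per_donor = pd.DataFrame(per_donor_rows)
    per_gene = (
        pd.Series({g: sum(1 for s in sites if s.site_class == "LSS") for g, sites in catalog.by_gene.items()})
        .rename_axis("gene")
        .reset_index(name="n_lss")
    )
    fractions = pd.DataFrame(
        [
            {
                "n_donors": len(per_donor),
                "fraction_with_stronger_lss": float(per_donor["stronger_lss_exists"].mean()) if len(per_donor) else 0.0,
                "n_lss_total": len(lss),
            }
        ]
    )
    return {
        "per_donor": per_donor,
        "extension_lengths": pd.DataFrame(length_rows),
        "per_gene": per_gene,
        "fractions": fractions,
    }
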