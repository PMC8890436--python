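"""Detection of activated latent/alternative donors from replicated RNA-seq.

The caller compares normalized latent usage (latent split reads over
canonical split reads for the same intron) between two case and two control
replicates, paired by replicate index.  A site passes the initial criteria
when one replicate shows at least 4 latent reads and a >=1.5-fold usage
increase while the other shows at least 1 latent read and any increase; the
stringent criteria impose the 4-read / 1.5-fold requirement on both
replicates.  Calls are then screened against per-base coverage of the exon
extension (reads present throughout, and consistently higher normalized
coverage in cases), ranked by one-sided Fisher's exact tests combined
across replicates with Fisher's method, and checked against a label-switch
negative control in which case and control labels are exchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import CandidateSite, SiteCatalog
from .junctions import CoverageProfile, JunctionCounts, UsageRecord, usage_ratio
from .stats import fisher_one_sided, fishers_method

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivationConfig:
    min_reads_primary: int = 4
    min_fold: float = 1.5
    min_reads_secondary: int = 1
    stringent: bool = False
    profile_presence_fraction: float = 1.0
    profile_higher_fraction: float = 0.95
    min_canonical_for_comparison: int = 10

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")
        for frac in (self.profile_presence_fraction, self.profile_higher_fraction):
            if not 0 < frac <= 1:
                raise ValueError("profile fractions must lie in (0, 1]")


@dataclass
class ReplicatePair:
    case: UsageRecord
    control: UsageRecord

    @property
    def defined(self) -> bool:
        return self.case.defined and self.control.defined

    @property
    def fold(self) -> float:
        """Usage fold change; +inf when control usage is 0 but case is not."""
        if not self.defined:
            return float("nan")
        if self.control.usage > 0:
            return self.case.usage / self.control.usage
        return math.inf if self.case.usage > 0 else 1.0


@dataclass
class ActivationCall:
    site: CandidateSite
    replicates: list[ReplicatePair]
    passes_initial: bool = False
    passes_stringent: bool = False
    profile_ok: bool = True
    rep_p: tuple[float, ...] = ()
    combined_p: float = float("nan")
    folds: tuple[float, ...] = ()
    fold_geomean: float = float("nan")
    label_switched: bool = False
    exclusion_reason: str = ""

    def called(self, cfg: ActivationConfig) -> bool:
        passes = self.passes_stringent if cfg.stringent else self.passes_initial
        return passes and self.profile_ok


def _meets(pair: ReplicatePair, min_reads: int, min_fold: float, strict: bool) -> bool:
    if pair.case.lss_reads < min_reads:
        return False
    fold = pair.fold
    return fold > min_fold if strict else fold >= min_fold


def check_initial_criteria(rep1: ReplicatePair, rep2: ReplicatePair, cfg: ActivationConfig) -> bool:
    """One replicate at >=4 reads and >=1.5-fold; the other at >=1 read and any increase.

    Either replicate may play the primary role.  All four usage values must
    be defined (canonical support in every sample); a control usage of 0
    with nonzero case usage satisfies any fold requirement.
    """
    if not (rep1.defined and rep2.defined):
        return False
    for primary, secondary in ((rep1, rep2), (rep2, rep1)):
        if _meets(primary, cfg.min_reads_primary, cfg.min_fold, strict=False) and _meets(
            secondary, cfg.min_reads_secondary, 1.0, strict=True
        ):
            return True
    return False


def check_stringent_criteria(rep1: ReplicatePair, rep2: ReplicatePair, cfg: ActivationConfig) -> bool:
    """Both replicates at >=4 latent reads and >=1.5-fold usage increase."""
    if not (rep1.defined and rep2.defined):
        return False
    return all(_meets(r, cfg.min_reads_primary, cfg.min_fold, strict=False) for r in (rep1, rep2))


def check_profile_support(
    case_profiles: Sequence[CoverageProfile],
    control_profiles: Sequence[CoverageProfile],
    cfg: ActivationConfig,
) -> bool:
    """Coverage evidence that the exon really extends to the latent donor.

    In every case replicate, at least ``profile_presence_fraction`` of
    extension positions must be covered (depth >= 1), and at least
    ``profile_higher_fraction`` of positions must show higher normalized
    depth in the case than in the replicate-paired control.  Control
    coverage may be absent entirely.
    """
    if len(case_profiles) != len(control_profiles):
        raise ValueError("case/control profile lists differ in length")
    for case, ctrl in zip(case_profiles, control_profiles):
        if len(case) != len(ctrl):
            raise ValueError("profile length mismatch between case and control")
        if len(case) == 0:
            return False
        presence = float(np.mean(case.depths >= 1.0))
        if presence < cfg.profile_presence_fraction:
            return False
        higher = float(np.mean(case.normalized > ctrl.normalized))
        if higher < cfg.profile_higher_fraction:
            return False
    return True


def _split_conditions(counts: Sequence[JunctionCounts], allow_any: bool = False):
    cases = sorted((c for c in counts if c.condition == "case"), key=lambda c: c.replicate)
    controls = sorted((c for c in counts if c.condition == "control"), key=lambda c: c.replicate)
    if not allow_any and (len(cases) != 2 or len(controls) != 2):
        raise ValueError(
            f"expected 2 case + 2 control samples, got {len(cases)} case / {len(controls)} control"
        )
    if len(cases) != len(controls) or not cases:
        raise ValueError("need equal, nonzero numbers of case and control replicates")
    return cases, controls


def _site_usage(site: CandidateSite, counts: JunctionCounts) -> UsageRecord:
    latent = (site.chrom, *site.latent_junction)
    canonical = (site.chrom, *site.canonical_junction)
    return usage_ratio(counts.get(latent), counts.get(canonical), site_key=site.key, sample_id=counts.sample_id)


def _geomean(folds: Sequence[float]) -> float:
    if any(math.isnan(f) for f in folds):
        return float("nan")
    if any(math.isinf(f) for f in folds):
        return math.inf
    if any(f <= 0 for f in folds):
        return 0.0
    return float(math.exp(sum(math.log(f) for f in folds) / len(folds)))


def call_activated(
    catalog: SiteCatalog,
    counts: Sequence[JunctionCounts],
    profiles: Mapping[tuple, CoverageProfile] | None = None,
    cfg: ActivationConfig = ActivationConfig(),
    allow_any_replicates: bool = False,
    label_switched: bool = False,
) -> list[ActivationCall]:
    """Run the activation pipeline over every site of a catalog.

    ``profiles`` maps (site.key, sample_id) to the coverage profile of the
    site's exon extension in that sample; when None, the profile screen is
    skipped (profile_ok=True).  Sites with undefined usage (no canonical
    split-read support) in any sample are retained with an exclusion reason
    and never pass.
    """
    cases, controls = _split_conditions(counts, allow_any_replicates)
    calls: list[ActivationCall] = []
    for site in catalog.sites:
        pairs = [
            ReplicatePair(case=_site_usage(site, ca), control=_site_usage(site, co))
            for ca, co in zip(cases, controls)
        ]
        call = ActivationCall(site=site, replicates=pairs, label_switched=label_switched)
        if not all(p.defined for p in pairs):
            call.exclusion_reason = "undefined_usage"
            calls.append(call)
            continue
        call.passes_initial = check_initial_criteria(pairs[0], pairs[1], cfg)
        call.passes_stringent = check_stringent_criteria(pairs[0], pairs[1], cfg)
        call.folds = tuple(p.fold for p in pairs)
        call.fold_geomean = _geomean(call.folds)
        call.rep_p = tuple(
            fisher_one_sided(
                [
                    [p.case.lss_reads, p.case.canonical_reads],
                    [p.control.lss_reads, p.control.canonical_reads],
                ]
            )
            for p in pairs
        )
        call.combined_p = fishers_method(call.rep_p)
        if profiles is not None and call.passes_initial:
            try:
                case_profiles = [profiles[(site.key, c.sample_id)] for c in cases]
                control_profiles = [profiles[(site.key, c.sample_id)] for c in controls]
            except KeyError:
                call.profile_ok = False
                call.exclusion_reason = "missing_profile"
            else:
                call.profile_ok = check_profile_support(case_profiles, control_profiles, cfg)
        calls.append(call)
    return calls


def label_switch(
    catalog: SiteCatalog,
    counts: Sequence[JunctionCounts],
    profiles: Mapping[tuple, CoverageProfile] | None = None,
    cfg: ActivationConfig = ActivationConfig(),
    allow_any_replicates: bool = False,
) -> list[ActivationCall]:
    """Re-run the pipeline with case and control labels exchanged."""
    swapped = [
        replace(c, condition={"case": "control", "control": "case"}.get(c.condition, c.condition))
        for c in counts
    ]
    return call_activated(
        catalog, swapped, profiles, cfg, allow_any_replicates, label_switched=True
    )


def rank_calls(calls: Sequence[ActivationCall], cfg: ActivationConfig = ActivationConfig()) -> pd.DataFrame:
    """Table of activated calls sorted by Fisher's-method combined p."""
    rows = []
    for call in calls:
        if not call.called(cfg):
            continue
        rows.append(
            {
                "chrom": call.site.chrom,
                "strand": call.site.strand,
                "gt_start": call.site.gt_start,
                "parent5ss": call.site.parent_donor,
                "gene": call.site.gene_id,
                "site_class": call.site.site_class,
                "extension_len": call.site.extension_length,
                "score": call.site.score,
                "p_rep1": call.rep_p[0],
                "p_rep2": call.rep_p[1] if len(call.rep_p) > 1 else float("nan"),
                "combined_p": call.combined_p,
                "fold_rep1": call.folds[0],
                "fold_rep2": call.folds[1] if len(call.folds) > 1 else float("nan"),
                "fold_geomean": call.fold_geomean,
                "stringent": call.passes_stringent,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "strand", "gt_start", "parent5ss", "gene", "site_class",
            "extension_len", "score", "p_rep1", "p_rep2", "combined_p",
            "fold_rep1", "fold_rep2", "fold_geomean", "stringent",
        ],
    )
    return df.sort_values("combined_p", kind="mergesort").reset_index(drop=True)


def build_comparison_set(
    catalog: SiteCatalog,
    control_counts: Sequence[JunctionCounts],
    min_canonical: int = 10,
) -> dict[tuple[str, str, int], CandidateSite]:
    """Highest-scoring LSS per donor with solid canonical support in all controls.

    Donors qualify when their canonical junction has at least
    ``min_canonical`` split reads in every control sample; each maps to its
    maximal-score LSS.
    """
    if not control_counts:
        raise ValueError("at least one control sample is required")
    best: dict[tuple[str, str, int], CandidateSite] = {}
    for donor_key, sites in catalog.by_donor.items():
        lss = [s for s in sites if s.site_class == "LSS"]
        if not lss:
            continue
        canonical = (lss[0].chrom, *lss[0].canonical_junction)
        if all(c.get(canonical) >= min_canonical for c in control_counts):
            best[donor_key] = max(lss, key=lambda s: s.score)
    return best


# ---------------------------------------------------------------------------
# composite coverage profiles


@dataclass
class CompositeProfile:
    """Median fold-difference profile across activated sites.

    ``median``, ``ci_low``, ``ci_high`` and ``n_sites`` are per-nucleotide
    arrays over positions measured from the annotated donor into the
    extension; the confidence band uses distribution-free order-statistic
    bounds for the median.  ``standardized`` holds one 100-bin average-fold
    row per site.
    """

    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_sites: np.ndarray
    standardized: pd.DataFrame
    degenerate: bool = False


def median_ci_bounds(n: int, confidence: float = 0.95) -> tuple[int, int]:
    """Order-statistic (binomial) rank bounds for a median CI; 0-based, inclusive."""
    alpha = (1 - confidence) / 2
    cdf = sps.binom.cdf(np.arange(n + 1), n, 0.5)
    lo_candidates = np.nonzero(cdf <= alpha)[0]
    lo = int(lo_candidates[-1] + 1) if len(lo_candidates) else 0
    hi_candidates = np.nonzero(cdf >= 1 - alpha)[0]
    hi = int(hi_candidates[0]) if len(hi_candidates) else n - 1
    return min(lo, n - 1), min(hi, n - 1)


def _site_fold_profile(
    site: CandidateSite,
    profiles: Mapping[tuple, CoverageProfile],
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    depth_floor: float = 1.0,
) -> np.ndarray:
    """Sense-oriented per-base fold (case over control), replicate-averaged.

    Raw depths are floored at one read-equivalent before normalization so
    the fold stays finite where the control lacks coverage.
    """
    folds = []
    for ca, co in zip(case_ids, control_ids):
        case = profiles[(site.key, ca)]
        ctrl = profiles[(site.key, co)]
        c = np.maximum(case.depths, depth_floor) / max(case.normalization, 1.0)
        t = np.maximum(ctrl.depths, depth_floor) / max(ctrl.normalization, 1.0)
        folds.append(c / t)
    fold = np.mean(folds, axis=0)
    return fold if site.strand == "+" else fold[::-1]


def standardize_profile(fold: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Mean fold within each of ``n_bins`` equal-width bins along the extension."""
    edges = np.linspace(0, len(fold), n_bins + 1)
    out = np.empty(n_bins)
    for i in range(n_bins):
        lo, hi = int(np.floor(edges[i])), int(np.ceil(edges[i + 1]))
        out[i] = float(np.mean(fold[lo:max(hi, lo + 1)]))
    return out


def composite_profile(
    calls: Sequence[ActivationCall],
    profiles: Mapping[tuple, CoverageProfile],
    counts: Sequence[JunctionCounts],
    cfg: ActivationConfig = ActivationConfig(),
    confidence: float = 0.95,
    n_bins: int = 100,
) -> CompositeProfile:
    """Composite fold-difference profile over all activated calls.

    Per site, per-base fold is the replicate-averaged ratio of normalized
    case to control depth (sense-oriented, measured from the annotated
    donor).  The composite is the pointwise median across sites, with a
    distribution-free 95% CI for the median; sites shorter than a position
    simply drop out of that position's median.
    """
    cases, controls = _split_conditions(counts, allow_any=True)
    case_ids = [c.sample_id for c in cases]
    control_ids = [c.sample_id for c in controls]
    active = [c for c in calls if c.called(cfg)]
    if not active:
        raise ValueError("no activated calls to compose")
    site_folds = {}
    std_rows = {}
    for call in active:
        fold = _site_fold_profile(call.site, profiles, case_ids, control_ids)
        site_folds[call.site.key] = fold
        std_rows[str(call.site.key)] = standardize_profile(fold, n_bins)
    max_len = max(len(f) for f in site_folds.values())
    median = np.full(max_len, np.nan)
    ci_low = np.full(max_len, np.nan)
    ci_high = np.full(max_len, np.nan)
    n_sites = np.zeros(max_len, dtype=int)
    for pos in range(max_len):
        vals = np.sort([f[pos] for f in site_folds.values() if len(f) > pos])
        n = len(vals)
        n_sites[pos] = n
        median[pos] = float(np.median(vals))
        lo, hi = median_ci_bounds(n, confidence)
        ci_low[pos] = vals[lo]
        ci_high[pos] = vals[hi]
    degenerate = len(active) < 3
    if degenerate:
        log.warning("composite profile over %d site(s): CI is degenerate", len(active))
    return CompositeProfile(
        median=median,
        ci_low=ci_low,
        ci_high=ci_high,
        n_sites=n_sites,
        standardized=pd.DataFrame.from_dict(std_rows, orient="index"),
        degenerate=degenerate,
    )
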