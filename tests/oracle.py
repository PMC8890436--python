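"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own parsing and enumeration code
paths: the GTF is parsed with naive line splitting, introns are scanned
with a regex, translation is a direct codon loop, the maximum-entropy fit
is a direct constrained optimization over the probability simplex, and the
one-sided Fisher p-value is a full hypergeometric enumeration with exact
integer arithmetic.
"""

from __future__ import annotations

import itertools
import math
import re
from fractions import Fraction

import numpy as np
from scipy.optimize import LinearConstraint, minimize

STOPS = {"TAA", "TAG", "TGA"}
_RC = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def parse_gtf_naive(path):
    """transcript_id -> dict(chrom, strand, gene, exons, cds) with half-open coords."""
    tx = {}
    for line in open(path):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if f[2] not in ("exon", "CDS"):
            continue
        attrs = dict(re.findall(r'(\w+) "([^"]*)"', f[8]))
        t = tx.setdefault(
            attrs["transcript_id"],
            {"chrom": f[0], "strand": f[6], "gene": attrs["gene_id"], "exons": [], "cds": []},
        )
        t["exons" if f[2] == "exon" else "cds"].append((int(f[3]) - 1, int(f[4])))
    for t in tx.values():
        t["exons"].sort()
        t["cds"].sort()
    return tx


def brute_force_catalog(gtf_path, genome, score_fn, threshold=0.0, max_ext=1000, min_res=20):
    """Site-for-site enumeration of the candidate catalog on a toy genome.

    Returns {(chrom, strand, gt_start, parent_donor): (site_class, extension,
    residual, score)} for candidates passing an inclusive score threshold.
    """
    tx = parse_gtf_naive(gtf_path)
    donors = set()
    for t in tx.values():
        for (s1, e1), (s2, e2) in zip(t["exons"], t["exons"][1:]):
            donors.add((t["chrom"], t["strand"], e1 if t["strand"] == "+" else s2 - 2))
    sites = {}
    for t in tx.values():
        if len(t["exons"]) < 2 or not t["cds"]:
            continue
        chrom, strand = t["chrom"], t["strand"]
        chrom_seq = str(genome[chrom][:]).upper()
        exons = t["exons"] if strand == "+" else list(reversed(t["exons"]))
        cds = t["cds"]

        def has_cds(exon):
            return any(exon[0] <= s and e <= exon[1] for s, e in cds)

        # cumulative CDS bases up to (sense) each exon end
        for i, (up, down) in enumerate(zip(exons, exons[1:])):
            if not (has_cds(up) and has_cds(down)):
                continue
            if strand == "+":
                gs, ge = up[1], down[0]
                intron = chrom_seq[gs:ge]
                donor_gt = gs
            else:
                gs, ge = down[1], up[0]
                intron = rc(chrom_seq[gs:ge])
                donor_gt = ge - 2
            cds_before = 0
            for s, e in cds:
                if strand == "+" and e <= up[1]:
                    cds_before += e - s
                if strand == "-" and s >= up[0]:
                    cds_before += e - s
            frame = cds_before % 3
            for m in re.finditer(r"(?=GT)", intron):
                d = m.start()
                if d < 1 or d > max_ext or len(intron) - d < min_res:
                    continue
                if strand == "+":
                    gt = gs + d
                else:
                    gt = ge - d - 2
                if (chrom, strand, gt) in donors:
                    continue
                if strand == "+":
                    window = chrom_seq[gt - 3 : gt + 6]
                else:
                    window = rc(chrom_seq[gt + 2 - 6 : gt + 2 + 3])
                if len(window) != 9 or "N" in window:
                    continue
                score = score_fn(window)
                if score < threshold:
                    continue
                ext = intron[:d]
                if strand == "+":
                    tail = chrom_seq[gs - frame : gs]
                else:
                    tail = rc(chrom_seq[ge : ge + frame])
                stop = naive_translate_has_stop(ext, frame, tail)
                if stop:
                    cls = "LSS"
                elif d % 3 == 0:
                    cls = "adSS_3n"
                else:
                    cls = "adSS_fs"
                key = (chrom, strand, gt, donor_gt)
                sites.setdefault(key, (cls, d, len(intron) - d, score))
    return sites


def naive_translate_has_stop(ext: str, frame: int, exon_tail: str) -> bool:
    """Direct codon walk through the extension continuing the exon frame."""
    seq = exon_tail[len(exon_tail) - frame :] + ext if frame else ext
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOPS and i + 3 > frame:  # at least one base in the extension
            return True
    return False


def maxent_simplex(training, constraint_sets, k, pseudocount=0.5):
    """Maximum entropy by direct numerical optimization over the simplex.

    Marginal-matching constraints are assembled as a linear system A p = b
    (with sum-to-one included), reduced to an independent row subset by
    pivoted QR (marginal constraints are mutually redundant), and handed to
    trust-region constrained minimization of the negative entropy.
    """
    from scipy.linalg import qr

    idx = {b: i for i, b in enumerate("ACGT")}
    enc = [[idx[c] for c in s] for s in training]
    space = list(itertools.product(range(4), repeat=k))
    n = 4**k

    rows = [np.ones(n)]
    rhs = [1.0]
    pseudo_mass = 4.0 * pseudocount
    for s in constraint_sets:
        s = tuple(sorted(s))
        counts = {}
        for row in enc:
            a = tuple(row[i] for i in s)
            counts[a] = counts.get(a, 0) + 1
        total = len(enc) + pseudo_mass
        for assign in itertools.product(range(4), repeat=len(s)):
            target = (counts.get(assign, 0) + pseudo_mass / 4 ** len(s)) / total
            indicator = np.array(
                [1.0 if all(x[p] == a for p, a in zip(s, assign)) else 0.0 for x in space]
            )
            rows.append(indicator)
            rhs.append(target)
    A = np.array(rows)
    b = np.array(rhs)
    rank = np.linalg.matrix_rank(A)
    _, _, piv = qr(A.T, pivoting=True)
    keep = sorted(piv[:rank])
    A, b = A[keep], b[keep]

    def neg_entropy(p):
        q = np.clip(p, 1e-300, None)
        return float(np.sum(q * np.log(q)))

    def neg_entropy_grad(p):
        q = np.clip(p, 1e-300, None)
        return np.log(q) + 1.0

    res = minimize(
        neg_entropy,
        np.full(n, 1.0 / n),
        jac=neg_entropy_grad,
        method="trust-constr",
        bounds=[(1e-15, 1.0)] * n,
        constraints=[LinearConstraint(A, b, b)],
        options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14},
    )
    assert res.status in (1, 2), res.message
    return res.x / res.x.sum()


def fisher_greater_exact(a, b, c, d) -> Fraction:
    """P(first cell >= a) over all tables with the observed margins, exact."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or (c + d) == 0 or (b + d) == 0:
        return Fraction(1)
    denom = math.comb(n, c1)
    total = Fraction(0)
    for x in range(a, min(r1, c1) + 1):
        if c1 - x <= n - r1:
            total += Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)
    return total
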