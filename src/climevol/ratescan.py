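"""Genome-wide substitution-rate scan and codon-based selection check.

For every gene tree (branch lengths in expected substitutions/site, sharing
an outgroup with the species tree) the scan reroots on the outgroup, drops
it, computes ingroup root-to-tip path sums — the per-lineage substitution-
rate proxy — and regresses them on an environmental covariate (e.g. yearly
hours above 30 °C of each species' range).  The per-gene slope signs and
significance counts summarise whether rate-environment coupling is genome
wide or driven by a few loci.

Genes whose slope deviates from the genome-wide pattern can be screened for
selection with a codon-based Z test (Nei-Gojobori pathway counting with
Jukes-Cantor correction, variance by bootstrap over codons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .treekit import Tree, drop_tip, reroot_on_outgroup, root_to_tip_paths

logger = logging.getLogger(__name__)

__all__ = [
    "ols_fit",
    "gene_rate_scan",
    "RateScanResult",
    "nei_gojobori_z",
    "CodonZResult",
]


def ols_fit(x, y):
    """Ordinary least squares with a two-sided t-test on the slope.

    Returns (slope, intercept, R^2, P).  Requires n >= 3 and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        # perfectly flat response: zero slope, nothing explained
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


@dataclass
class RateScanResult:
    """Per-gene regression table and sign/significance tallies."""

    per_gene: pd.DataFrame  # gene, n_tips, slope, r2, pvalue
    alpha: float
    n_skipped: int

    @property
    def n_genes(self) -> int:
        return len(self.per_gene)

    @property
    def n_positive(self) -> int:
        return int((self.per_gene["slope"] > 0).sum())

    @property
    def n_negative(self) -> int:
        return int((self.per_gene["slope"] < 0).sum())

    @property
    def n_zero(self) -> int:
        return int((self.per_gene["slope"] == 0).sum())

    @property
    def n_positive_significant(self) -> int:
        df = self.per_gene
        return int(((df["slope"] > 0) & (df["pvalue"] < self.alpha)).sum())

    @property
    def n_negative_significant(self) -> int:
        df = self.per_gene
        return int(((df["slope"] < 0) & (df["pvalue"] < self.alpha)).sum())

    def summary(self) -> str:
        return (
            f"rate scan over {self.n_genes} genes ({self.n_skipped} skipped): "
            f"{self.n_positive} positive slopes ({self.n_positive_significant} at P < {self.alpha:g}), "
            f"{self.n_negative} negative ({self.n_negative_significant} significant), "
            f"{self.n_zero} zero"
        )

    def to_frame(self) -> pd.DataFrame:
        return self.per_gene.copy()


def gene_rate_scan(
    genes: dict[str, Tree],
    env: dict[str, float],
    outgroup: str,
    alpha: float = 0.05,
) -> RateScanResult:
    """Regress per-gene ingroup root-to-tip paths on an environment covariate.

    Per gene: reroot on the outgroup, drop it, sum branch lengths root-to-tip
    for each ingroup tip present, and fit OLS of path on env over the tips
    present in that gene (tips without an env value are dropped per gene).
    Genes lacking the outgroup or with fewer than 3 usable tips are skipped
    with a warning.  Tallies partition the retained genes by slope sign, with
    significance at the stated threshold (default P < 0.05).
    """
    rows = []
    n_skipped = 0
    for gid in sorted(genes):
        gtree = genes[gid]
        if outgroup not in gtree.tip_labels:
            logger.warning("gene %s lacks outgroup %r; skipped", gid, outgroup)
            n_skipped += 1
            continue
        rooted = reroot_on_outgroup(gtree, outgroup)
        ingroup = drop_tip(rooted, outgroup)
        paths = root_to_tip_paths(ingroup)
        usable = [sp for sp in paths if sp in env and not pd.isna(env[sp])]
        if len(usable) < 3:
            logger.warning("gene %s has %d usable tips; skipped", gid, len(usable))
            n_skipped += 1
            continue
        x = [env[sp] for sp in usable]
        y = [paths[sp] for sp in usable]
        slope, _, r2, p = ols_fit(x, y)
        rows.append({"gene": gid, "n_tips": len(usable), "slope": slope, "r2": r2, "pvalue": p})
    per_gene = pd.DataFrame(rows, columns=["gene", "n_tips", "slope", "r2", "pvalue"])
    return RateScanResult(per_gene=per_gene, alpha=alpha, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Nei-Gojobori codon Z test
# ---------------------------------------------------------------------------

_BASES = "TCAG"


def _codon_table():
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


_AA = None


def _aa(codon: str) -> str | None:
    global _AA
    if _AA is None:
        _AA = _codon_table()
    return _AA.get(codon)


def _syn_sites(codon: str) -> float:
    """Nei-Gojobori synonymous site count of one codon (0..3)."""
    aa0 = _aa(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mutant) == "*":
                continue
            if _aa(mutant) == aa0:
                syn += 1
        s += syn / 3.0
    return s


def _path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons,
    averaged over all mutational pathways that avoid stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot, nsyn_tot, n_paths = 0.0, 0.0, 0
    for order in permutations(diff_pos):
        cur = c1
        syn, nsyn = 0, 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                blocked = True
                break
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if not blocked:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        # every pathway passes through a stop; count all changes nonsynonymous
        return 0.0, float(len(diff_pos))
    return syn_tot / n_paths, nsyn_tot / n_paths


def _jc(p: float) -> float:
    if p >= 0.75:
        raise ValueError("proportion too large for Jukes-Cantor correction")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@dataclass
class CodonZResult:
    """Codon-based Z test of neutrality (dN = dS), overall averages."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    dS: float
    dN: float
    Z: float
    P: float
    n_codons: int
    n_skipped_codons: int
    identical: bool = False

    def summary(self) -> str:
        if self.identical:
            return "sequences identical: dN = dS = 0, neutrality not testable (P = 1)"
        return (
            f"Nei-Gojobori Z test over {self.n_codons} codons: dN = {self.dN:.4f}, "
            f"dS = {self.dS:.4f}, Z = {self.Z:.3f}, P = {self.P:.4g}"
        )


def _pair_counts(codons1, codons2):
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons1, codons2):
        sa, sb = _syn_sites(ca), _syn_sites(cb)
        S += 0.5 * (sa + sb)
        N += 3.0 - 0.5 * (sa + sb)
        sd, nd = _path_differences(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def nei_gojobori_z(
    sequences: list[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> CodonZResult:
    """Codon-based Z test of selection on overall pairwise averages.

    Nei-Gojobori (1986) pathway counting of synonymous and nonsynonymous
    sites and differences, averaged over all sequence pairs; proportions are
    Jukes-Cantor corrected; Z = (dN - dS)/SE with the SE estimated by a
    seeded bootstrap over codon columns; two-sided P against dN = dS.
    Codons containing ambiguity characters or gaps are skipped (counted).
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must have equal length")
    if L % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    seqs = [s.upper().replace("U", "T") for s in sequences]

    n_codons_total = L // 3
    keep, skipped = [], 0
    for k in range(n_codons_total):
        cods = [s[3 * k : 3 * k + 3] for s in seqs]
        if all(all(b in _BASES for b in c) for c in cods):
            if any(_aa(c) == "*" for c in cods):
                raise ValueError(f"internal stop codon at codon {k + 1}")
            keep.append(k)
        else:
            skipped += 1
    if not keep:
        raise ValueError("no analysable codons")
    codon_lists = [[s[3 * k : 3 * k + 3] for k in keep] for s in seqs]

    pairs = [(i, j) for i in range(len(seqs)) for j in range(i + 1, len(seqs))]

    def _averages(indices):
        S = N = Sd = Nd = 0.0
        for i, j in pairs:
            ci = [codon_lists[i][k] for k in indices]
            cj = [codon_lists[j][k] for k in indices]
            s, n, sd, nd = _pair_counts(ci, cj)
            S += s
            N += n
            Sd += sd
            Nd += nd
        m = len(pairs)
        return S / m, N / m, Sd / m, Nd / m

    all_idx = list(range(len(keep)))
    S, N, Sd, Nd = _averages(all_idx)
    if Sd == 0 and Nd == 0:
        return CodonZResult(
            syn_sites=S, nonsyn_sites=N, syn_diffs=0.0, nonsyn_diffs=0.0,
            dS=0.0, dN=0.0, Z=0.0, P=1.0, n_codons=len(keep),
            n_skipped_codons=skipped, identical=True,
        )
    dS = _jc(Sd / S) if S > 0 else 0.0
    dN = _jc(Nd / N) if N > 0 else 0.0

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(keep), size=len(keep))
        Sb, Nb, Sdb, Ndb = _averages(idx)
        try:
            d = (_jc(Ndb / Nb) if Nb > 0 else 0.0) - (_jc(Sdb / Sb) if Sb > 0 else 0.0)
        except ValueError:
            continue
        boots.append(d)
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan
    if not np.isfinite(se) or se == 0:
        z, p = np.inf if dN != dS else 0.0, 0.0 if dN != dS else 1.0
    else:
        z = (dN - dS) / se
        p = float(2 * stats.norm.sf(abs(z)))
    return CodonZResult(
        syn_sites=S, nonsyn_sites=N, syn_diffs=Sd, nonsyn_diffs=Nd,
        dS=dS, dN=dN, Z=float(z), P=p, n_codons=len(keep),
        n_skipped_codons=skipped,
    )
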