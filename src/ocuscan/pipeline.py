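"""Genome-level detection of translational selection and per-gene OCU calls.

Per window size, the paired cross-validation yields 50 AUC pairs and, for
every gene, 50 probability pairs (baseline vs codon-augmented arm). The
genome-level question — does codon usage carry information beyond the
local intergenic composition? — is answered by a one-sided sign test on
the AUC pairs. The gene-level question — is *this* gene's codon usage
shifted toward the ribosomal-protein profile? — by a sign test on its
probability pairs; the calls from the 5, 10 and 20 kb windows are combined
into a consensus by taking the median of the three p-values. At the
default threshold of 1e-15 a gene is called OCU (optimized codon usage)
only when at least two windows recorded a probability increase in every
single one of the 50 runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .codes import genetic_code, revcomp
from .features import build_datasets
from .rf import CVConfig, PairedCVResult, paired_cv
from .stats import (
    Contingency2x2,
    ContingencyResult,
    PairedComparison,
    TestResult,
    bws_test,
    corrected_resampled_ttest,
    fisher_exact,
    mann_whitney,
    permutation_pvalue,
    sign_test,
)

DEFAULT_WINDOWS = (5, 10, 20)
DEFAULT_THRESHOLD = 1e-15


@dataclass
class WindowReport:
    """Outcome of the paired protocol at one window size."""

    window_kb: float
    result: PairedCVResult
    sign: TestResult
    corrected_t: TestResult
    excluded: list

    @property
    def mean_auc_baseline(self):
        return float(self.result.auc_baseline.mean())

    @property
    def mean_auc_augmented(self):
        return float(self.result.auc_augmented.mean())


@dataclass
class GenomeReport:
    """Full detection report for one genome."""

    genome_id: str
    windows: dict  # window_kb -> WindowReport
    ocu: pd.DataFrame  # per-gene calls
    threshold: float
    selection_detected: bool
    pct_ocu: float
    cv_metadata: dict


def detect_selection(result: PairedCVResult, test_fraction: float):
    """Genome-level tests on the 50 paired AUCs of one window.

    Returns ``(sign, corrected_t)``: the one-sided sign test on
    augmented-vs-baseline AUC wins, and the corrected resampled t-test on
    the AUC differences (the conservative companion).
    """
    comp = PairedComparison.from_pairs(result.auc_augmented, result.auc_baseline)
    s = sign_test(comp)
    t = corrected_resampled_ttest(
        result.auc_augmented - result.auc_baseline, test_fraction
    )
    return s, t


def run_window(genome, window_kb, cv: CVConfig, *, masks=None, table_id=11) -> WindowReport:
    """Build datasets and run the paired protocol at one window size."""
    baseline, augmented, excluded = build_datasets(
        genome, window_kb, masks=masks, table_id=table_id
    )
    result = paired_cv(baseline, augmented, cv)
    test_fraction = 1.0 / (cv.n_folds - 1)
    s, t = detect_selection(result, test_fraction)
    return WindowReport(window_kb, result, s, t, excluded)


def gene_sign_pvalues(result: PairedCVResult):
    """Per-gene one-sided sign test on the 50 paired probabilities."""
    wins = (result.prob_augmented > result.prob_baseline).sum(axis=1)
    losses = (result.prob_augmented < result.prob_baseline).sum(axis=1)
    out = np.empty(len(result.gene_ids))
    for i, (w, l) in enumerate(zip(wins, losses)):
        out[i] = sign_test(PairedComparison(int(w), int(l))).p
    return out


def call_ocu(window_results: dict, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Consensus per-gene OCU calls across window sizes.

    ``window_results`` maps window size to :class:`PairedCVResult`. The
    consensus p is the median of a gene's per-window sign-test p-values;
    genes missing from a window (no intergenic DNA there) fall back to the
    median of the windows where they were testable. A gene absent from
    every window is reported with NaN consensus and ``is_ocu = False``.
    """
    all_genes: list = []
    seen = set()
    for res in window_results.values():
        for gid in res.gene_ids:
            if gid not in seen:
                seen.add(gid)
                all_genes.append(gid)
    per_window = {}
    corrected = {}
    for wkb, res in window_results.items():
        p = gene_sign_pvalues(res)
        diffs = res.prob_augmented - res.prob_baseline
        tf = 1.0 / (res.config.n_folds - 1) if res.config else 1.0 / 3
        tp = np.array(
            [corrected_resampled_ttest(d, tf).p for d in diffs]
        )
        per_window[wkb] = dict(zip(res.gene_ids, p))
        corrected[wkb] = dict(zip(res.gene_ids, tp))
    rows = []
    for gid in all_genes:
        ps = {wkb: per_window[wkb][gid] for wkb in window_results if gid in per_window[wkb]}
        tps = [corrected[wkb][gid] for wkb in window_results if gid in corrected[wkb]]
        consensus = float(np.median(list(ps.values()))) if ps else float("nan")
        row = {"gene_id": gid}
        for wkb in window_results:
            row[f"p_{wkb}k"] = ps.get(wkb, float("nan"))
        row["p_consensus"] = consensus
        row["p_corrected_t"] = float(np.median(tps)) if tps else float("nan")
        row["n_windows"] = len(ps)
        row["is_ocu"] = bool(ps) and consensus <= threshold
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_genome(
    genome,
    *,
    windows=DEFAULT_WINDOWS,
    cv: CVConfig = None,
    threshold: float = DEFAULT_THRESHOLD,
    masks=None,
    table_id: int = 11,
    genome_id: str = "genome",
) -> GenomeReport:
    """Run the full detection protocol on one genome.

    Each window size gets its own fold-partition seed stream (offset from
    ``cv.base_seed``) but within a window the two arms share partitions.
    ``selection_detected`` is the consensus across windows: the median of
    the per-window AUC sign-test p-values at or below ``threshold``.
    """
    cv = cv or CVConfig()
    reports = {}
    for wi, wkb in enumerate(windows):
        cv_w = replace(cv, base_seed=cv.base_seed + 1009 * wi)
        reports[wkb] = run_window(genome, wkb, cv_w, masks=masks, table_id=table_id)
    ocu = call_ocu({wkb: rep.result for wkb, rep in reports.items()}, threshold)
    rp = {g.gene_id: g.is_rp for g in genome.genes}
    ocu["is_rp"] = ocu.gene_id.map(rp)
    detection_p = float(np.median([rep.sign.p for rep in reports.values()]))
    called = ocu[ocu.n_windows > 0]
    pct = 100.0 * called.is_ocu.mean() if len(called) else float("nan")
    return GenomeReport(
        genome_id=genome_id,
        windows=reports,
        ocu=ocu,
        threshold=threshold,
        selection_detected=detection_p <= threshold,
        pct_ocu=float(pct),
        cv_metadata=cv.metadata(),
    )


# ---------------------------------------------------------------------------
# Optimal-codon analysis


def optimal_codon_analysis(
    ocu_table: pd.DataFrame,
    genes,
    trna_inventory: dict,
    *,
    table_id: int = 11,
    p_threshold: float = 1e-3,
) -> pd.DataFrame:
    """Do OCU genes prefer the tRNA-matched codon of two-fold amino acids?

    For every two-fold degenerate amino acid whose genome encodes tRNAs
    with exactly one of the two anticodons, the optimal codon is the
    Watson-Crick match of that anticodon (no wobble). The within-family
    frequency of the optimal codon is compared between OCU and non-OCU
    genes by a two-sided Mann-Whitney U test; at ``p_threshold`` the
    outcome is "optimal", "suboptimal" or "none". Amino acids with both
    (or neither) anticodon present are reported as "undefined".
    """
    code = genetic_code(table_id)
    ocu_ids = set(ocu_table.loc[ocu_table.is_ocu, "gene_id"])
    called = set(ocu_table.gene_id)
    rows = []
    for aa in code.twofold_amino_acids:
        fam = code.families[aa]
        anticodons = trna_inventory.get(aa, ())
        matched = [c for c in fam if revcomp(c) in set(anticodons)]
        if len(matched) != 1:
            reason = "both anticodons present" if len(matched) == 2 else "no anticodon"
            rows.append(
                {"amino_acid": aa, "optimal_codon": None, "suboptimal_codon": None,
                 "n_ocu": 0, "n_non_ocu": 0, "p": float("nan"),
                 "outcome": "undefined", "note": reason}
            )
            continue
        optimal = matched[0]
        suboptimal = fam[0] if fam[1] == optimal else fam[1]
        x, y = [], []  # optimal-codon frequency in OCU / non-OCU genes
        for g in genes:
            if g.gene_id not in called:
                continue
            n_opt = sum(c == optimal for c in g.codons)
            n_sub = sum(c == suboptimal for c in g.codons)
            if n_opt + n_sub == 0:
                continue
            freq = n_opt / (n_opt + n_sub)
            (x if g.gene_id in ocu_ids else y).append(freq)
        if not x or not y:
            rows.append(
                {"amino_acid": aa, "optimal_codon": optimal, "suboptimal_codon": suboptimal,
                 "n_ocu": len(x), "n_non_ocu": len(y), "p": float("nan"),
                 "outcome": "undefined", "note": "one group empty"}
            )
            continue
        res = mann_whitney(x, y)
        if res.p < p_threshold and res.direction == "x":
            outcome = "optimal"
        elif res.p < p_threshold and res.direction == "y":
            outcome = "suboptimal"
        else:
            outcome = "none"
        rows.append(
            {"amino_acid": aa, "optimal_codon": optimal, "suboptimal_codon": suboptimal,
             "n_ocu": len(x), "n_non_ocu": len(y), "p": res.p,
             "outcome": outcome, "note": ""}
        )
    return pd.DataFrame(rows)


def preference_sign_test(tallies) -> TestResult:
    """Cross-genome sign test on optimal vs suboptimal preferences.

    ``tallies`` is an iterable of outcome strings ("optimal"/"suboptimal"/
    other); the null is that a preferring genome is equally likely to
    prefer either codon.
    """
    wins = sum(t == "optimal" for t in tallies)
    losses = sum(t == "suboptimal" for t in tallies)
    return sign_test(PairedComparison(wins, losses))


# ---------------------------------------------------------------------------
# Enrichment tests


@dataclass
class EnrichmentResult:
    category: str
    lifestyle: str
    result: ContingencyResult
    passes_screen: bool


def _screen(res: ContingencyResult, p_threshold, lo, hi) -> bool:
    r = res.ratio
    return res.p < p_threshold and np.isfinite(r) and (r > hi or r < lo)


def enrichment_test_a(
    calls: pd.DataFrame,
    membership: dict,
    category: str,
    *,
    p_threshold: float = 1e-3,
    ratio_low: float = 0.67,
    ratio_high: float = 1.50,
) -> EnrichmentResult:
    """Test A: OCU rate inside one category vs outside, pooled over genomes.

    ``calls`` needs columns gene_uid and is_ocu; ``membership`` maps
    gene_uid to a set of category labels. The screen keeps tests with
    p < 1e-3 and enrichment ratio > 1.50 or < 0.67; the full result is
    returned either way with ``passes_screen`` set.
    """
    in_cat = calls.gene_uid.map(lambda g: category in membership.get(g, ()))
    a = int((in_cat & calls.is_ocu).sum())
    b = int((in_cat & ~calls.is_ocu).sum())
    c = int((~in_cat & calls.is_ocu).sum())
    d = int((~in_cat & ~calls.is_ocu).sum())
    if a + b == 0:
        raise ValueError(f"category {category!r} is empty")
    res = fisher_exact(Contingency2x2(a, b, c, d))
    return EnrichmentResult(category, "", res, _screen(res, p_threshold, ratio_low, ratio_high))


def enrichment_test_b(
    calls: pd.DataFrame,
    membership: dict,
    lifestyles: dict,
    category: str,
    lifestyle: str,
    *,
    p_threshold: float = 1e-3,
    ratio_low: float = 0.67,
    ratio_high: float = 1.50,
) -> EnrichmentResult:
    """Test B: within one category, OCU rate in lifestyle vs non-lifestyle
    organisms.

    ``calls`` needs columns gene_uid, genome_id, is_ocu; ``lifestyles``
    maps genome_id to "has"/"lacks"/"unknown" (unknown genomes excluded).
    """
    sub = calls[calls.gene_uid.map(lambda g: category in membership.get(g, ()))]
    if len(sub) == 0:
        raise ValueError(f"category {category!r} absent from all genomes")
    status = sub.genome_id.map(lambda gid: lifestyles.get(gid, "unknown"))
    has, lacks = sub[status == "has"], sub[status == "lacks"]
    a, b = int(has.is_ocu.sum()), int((~has.is_ocu).sum())
    c, d = int(lacks.is_ocu.sum()), int((~lacks.is_ocu).sum())
    res = fisher_exact(Contingency2x2(a, b, c, d))
    return EnrichmentResult(
        category, lifestyle, res, _screen(res, p_threshold, ratio_low, ratio_high)
    )


# ---------------------------------------------------------------------------
# Expression contrast


@dataclass
class ExpressionContrast:
    ratio_of_means: float
    bws: TestResult
    ratio_permutation_p: float
    n_ocu: int
    n_non_ocu: int


def expression_contrast(
    ocu_table: pd.DataFrame,
    expression: dict,
    *,
    exclude_rp: bool = False,
    n_perm: int = 2000,
    seed: int = 0,
) -> ExpressionContrast:
    """Compare user-supplied expression values of OCU vs non-OCU genes.

    Reports mean(OCU)/mean(non-OCU), the two-sided BWS permutation p for a
    distributional shift, and a one-sided permutation p for the ratio
    exceeding unity. ``expression`` maps gene_id to a nonnegative value;
    genes without a value are skipped (a warning is issued when more than
    half are missing).
    """
    import warnings

    table = ocu_table[ocu_table.n_windows > 0] if "n_windows" in ocu_table else ocu_table
    if exclude_rp and "is_rp" in table:
        table = table[~table.is_rp]
    have = table.gene_id.map(lambda g: g in expression)
    if have.mean() < 0.5:
        warnings.warn("expression values missing for more than half of the genes")
    table = table[have]
    vals = table.gene_id.map(expression).to_numpy(dtype=float)
    is_ocu = table.is_ocu.to_numpy(dtype=bool)
    x, y = vals[is_ocu], vals[~is_ocu]
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one OCU and one non-OCU gene with expression")
    ratio = float(x.mean() / y.mean())
    b = bws_test(x, y, seed=seed)
    perm_p = permutation_pvalue(
        vals, is_ocu, lambda a, bb: a.mean() / bb.mean(), n_perm=n_perm, seed=seed + 1
    )
    return ExpressionContrast(ratio, b, perm_p, int(x.size), int(y.size))
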