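"""Mutation-spectrum analyses over pass-filter duplex calls.

All analyses share one normalization principle: a frequency is a count of
variant observations divided by the duplex consensus coverage of exactly the
sites where such an observation could have been made — coverage of a region,
of the bases of one strand of a gene, or of one trinucleotide context.  This
keeps frequencies comparable between regions/contexts with very different
base compositions.

Substitutions are collapsed onto the six pyrimidine-keyed classes (C>A, C>G,
C>T, T>A, T>C, T>G): a G>A change on the reference plus strand is the same
molecular event as C>T read on the minus strand.  Strand-asymmetry analyses
then re-expand a collapsed class onto the template / non-template strands of
the containing gene: C>T whose pyrimidine sits on the gene's sense strand
reads as C>T on the non-template strand, otherwise it reads as G>A there.

Statistical comparisons are thin calls to scipy/statsmodels routines
(t-tests, paired Wilcoxon signed-rank, Kruskal-Wallis, one-way ANOVA with
Tukey HSD); no multiple-testing correction is applied by default, with a
Benjamini-Hochberg option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .duplexcall import PASS, CoverageProfile, DuplexCallResult, VariantCall
from .orgmodel import revcomp
from .synth import CLASSES

TRANSITIONS = ("C>T", "T>C")
_PYRIMIDINES = "CT"


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Collapse a substitution onto its pyrimidine-keyed class.

    Returns (class, strand of the pyrimidine on the reference): purine
    reference changes are reported as the complementary pyrimidine change
    with the strand flag flipped, e.g. (G, A) -> ("C>T", "-").
    """
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    if ref in _PYRIMIDINES:
        return f"{ref}>{alt}", "+"
    return f"{revcomp(ref)}>{revcomp(alt)}", "-"


def is_transition(cls: str) -> bool:
    return cls in TRANSITIONS


def _pass_snvs(calls: list[VariantCall]) -> list[VariantCall]:
    return [c for c in calls if c.status == PASS and c.vtype == "SNV"]


def class_spectrum(replicates: list[DuplexCallResult]) -> pd.DataFrame:
    """Six-class spectrum: per replicate, count / total coverage per class."""
    rows = []
    for i, rep in enumerate(replicates):
        total = rep.coverage.total()
        counts = {c: 0 for c in CLASSES}
        for call in _pass_snvs(rep.calls):
            cls, _ = classify_substitution(call.ref, call.alt)
            counts[cls] += 1
        for cls in CLASSES:
            rows.append(
                {
                    "replicate": i,
                    "class": cls,
                    "transition": is_transition(cls),
                    "count": counts[cls],
                    "coverage": total,
                    "frequency": counts[cls] / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def region_frequencies(
    replicates: list[DuplexCallResult],
    class_filter: str | None = None,
    run_test: bool = True,
) -> tuple[pd.DataFrame, dict | None]:
    """Per-region variant frequencies and a Kruskal-Wallis test across regions.

    Regions with zero coverage in a replicate are flagged (NaN frequency) and
    excluded from the test.
    """
    rows = []
    for i, rep in enumerate(replicates):
        region_cov = rep.coverage.region_coverage()
        counts: dict[str, int] = {r: 0 for r in region_cov}
        for call in _pass_snvs(rep.calls):
            if class_filter is not None:
                cls, _ = classify_substitution(call.ref, call.alt)
                if cls != class_filter:
                    continue
            counts[call.region] += 1
        for region, cov in region_cov.items():
            rows.append(
                {
                    "replicate": i,
                    "region": region,
                    "count": counts[region],
                    "coverage": cov,
                    "frequency": counts[region] / cov if cov else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    test = None
    if run_test:
        groups = [
            g.frequency.dropna().to_numpy()
            for _, g in df.groupby("region")
            if g.frequency.notna().any()
        ]
        groups = [g for g in groups if len(g)]
        if len(groups) >= 2:
            try:
                stat, p = stats.kruskal(*groups)
                test = {"test": "kruskal", "statistic": float(stat), "p": float(p)}
            except ValueError:  # all values identical
                test = {"test": "kruskal", "statistic": np.nan, "p": 1.0}
    return df, test


def strand_assignment(call: VariantCall) -> tuple[str, str] | None:
    """How a collapsed-class SNV reads on the non-template strand of its gene.

    Returns (collapsed class, reading) where reading is the substitution as
    written on the non-template (sense) strand, or None for calls outside
    single-strand genic features.  The template strand is the strand RNA
    polymerase reads, i.e. the reverse complement of the gene's sense strand.
    """
    if call.region == "intergenic" or call.gene_strand not in ("+", "-"):
        return None
    cls, pyr_strand = classify_substitution(call.ref, call.alt)
    if pyr_strand == call.gene_strand:
        reading = cls  # pyrimidine change sits on the sense = non-template strand
    else:
        a, b = cls.split(">")
        reading = f"{revcomp(a)}>{revcomp(b)}"
    return cls, reading


def strand_asymmetry(
    replicates: list[DuplexCallResult],
    collapsed_class: str = "C>T",
    test: str = "wilcoxon",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Template/non-template asymmetry of one collapsed substitution class.

    For each genic region, computes the frequency of the pyrimidine change as
    read on the non-template strand (e.g. C>T) vs the complementary purine
    change there (G>A), each normalized by the non-template-strand coverage
    of its source base.  Sites inside features on both strands are excluded.

    Returns (tidy per-replicate table, per-region paired-test table); the
    paired test is the Wilcoxon signed-rank by default or a paired t-test
    with ``test="ttest"``.
    """
    if collapsed_class not in CLASSES:
        raise ValueError(f"unknown class {collapsed_class}")
    pyr = collapsed_class[0]
    a, b = collapsed_class.split(">")
    purine_reading = f"{revcomp(a)}>{revcomp(b)}"
    rows = []
    for i, rep in enumerate(replicates):
        sbc = rep.coverage.strand_base_coverage()
        sbc = sbc[sbc.pyrimidine == pyr]
        # source base on the non-template strand:
        #   pyrimidine reading (C>T): pyrimidine on sense strand -> on_template False
        #   purine reading (G>A): pyrimidine on template strand -> on_template True
        cov_pyr = sbc[~sbc.on_template].set_index("region")["coverage"]
        cov_pur = sbc[sbc.on_template].set_index("region")["coverage"]
        counts: dict[tuple[str, str], int] = {}
        for call in _pass_snvs(rep.calls):
            assigned = strand_assignment(call)
            if assigned is None:
                continue
            cls, reading = assigned
            if cls != collapsed_class:
                continue
            counts[(call.region, reading)] = counts.get((call.region, reading), 0) + 1
        regions = sorted(set(cov_pyr.index) | set(cov_pur.index))
        for region in regions:
            for reading, cov_series in (
                (collapsed_class, cov_pyr),
                (purine_reading, cov_pur),
            ):
                cov = int(cov_series.get(region, 0))
                cnt = counts.get((region, reading), 0)
                rows.append(
                    {
                        "replicate": i,
                        "region": region,
                        "reading": reading,
                        "count": cnt,
                        "coverage": cov,
                        "frequency": cnt / cov if cov else np.nan,
                    }
                )
    df = pd.DataFrame(rows)
    tests = []
    if len(df):
        for region, g in df.groupby("region"):
            wide = g.pivot(index="replicate", columns="reading", values="frequency")
            if wide.shape[1] != 2 or wide.dropna().shape[0] < 2:
                continue
            wide = wide.dropna()
            x = wide[collapsed_class].to_numpy()
            y = wide[purine_reading].to_numpy()
            res = paired_test(x, y, test)
            res["region"] = region
            tests.append(res)
    return df, pd.DataFrame(tests)


def paired_test(x: np.ndarray, y: np.ndarray, test: str = "wilcoxon") -> dict:
    """Paired comparison of complementary-class frequencies per replicate."""
    if len(x) != len(y) or len(x) < 2:
        return {"test": test, "statistic": np.nan, "p": np.nan, "skipped": "too few pairs"}
    d = x - y
    if test == "ttest":
        if np.allclose(d.std(ddof=1), 0):
            p = 1.0 if np.allclose(d, 0) else 0.0
            return {"test": "ttest", "statistic": np.nan, "p": p}
        stat, p = stats.ttest_rel(x, y)
    elif test == "wilcoxon":
        if np.allclose(d, 0):
            return {"test": "wilcoxon", "statistic": np.nan, "p": 1.0}
        stat, p = stats.wilcoxon(x, y)
    else:
        raise ValueError(f"unknown paired test {test!r}")
    return {"test": test, "statistic": float(stat), "p": float(p)}


def trinucleotide_frequencies(
    replicates: list[DuplexCallResult],
    collapsed_class: str = "C>T",
) -> pd.DataFrame:
    """Coverage-normalized frequency per 16 trinucleotide contexts.

    Contexts are taken on the strand of the pyrimidine; the denominator is
    the duplex coverage of sites with that context, so frequencies are not
    inflated in contexts that are common in the genome.  Contexts with zero
    coverage are flagged (NaN).
    """
    if collapsed_class not in CLASSES:
        raise ValueError(f"unknown class {collapsed_class}")
    pyr = collapsed_class[0]
    rows = []
    for i, rep in enumerate(replicates):
        ctx_cov = rep.coverage.context_coverage(pyr)
        counts = {ctx: 0 for ctx in ctx_cov}
        for call in _pass_snvs(rep.calls):
            cls, _ = classify_substitution(call.ref, call.alt)
            if cls != collapsed_class or call.context is None:
                continue
            if call.context in counts:
                counts[call.context] += 1
        for ctx, cov in ctx_cov.items():
            rows.append(
                {
                    "replicate": i,
                    "context": ctx,
                    "fivep": ctx[0],
                    "threep": ctx[2],
                    "count": counts[ctx],
                    "coverage": cov,
                    "frequency": counts[ctx] / cov if cov else np.nan,
                }
            )
    return pd.DataFrame(rows)


def fold_enrichment(
    num_a: float | np.ndarray,
    den_a: float | np.ndarray,
    num_b: float | np.ndarray,
    den_b: float | np.ndarray,
) -> float:
    """Ratio of pooled frequencies: (sum num_a/sum den_a)/(sum num_b/sum den_b).

    Counts and coverages are pooled *before* division (robust to empty
    replicate cells); the mean of per-replicate ratios is deliberately not
    used.  Undefined denominators yield NaN.
    """
    na, da = float(np.sum(num_a)), float(np.sum(den_a))
    nb, db = float(np.sum(num_b)), float(np.sum(den_b))
    if da <= 0 or db <= 0 or nb <= 0:
        return float("nan")
    return (na / da) / (nb / db)


def context_family_enrichment(tri: pd.DataFrame, fivep_bases: str = "CT") -> float:
    """Pooled fold enrichment of contexts whose 5' base is in ``fivep_bases``
    relative to the remaining contexts (e.g. 5'-pyrimidine YCN vs RCN)."""
    sel = tri.fivep.isin(list(fivep_bases))
    a, b = tri[sel], tri[~sel]
    return fold_enrichment(a["count"], a.coverage, b["count"], b.coverage)


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p: float
    direction: str | None = None
    detail: object = None
    skipped: str | None = None


def group_tests(
    group_a: np.ndarray,
    group_b: np.ndarray | None = None,
    groups: list[np.ndarray] | None = None,
    test: str = "ttest",
) -> GroupTestResult:
    """Thin dispatch to the standard group-comparison routines.

    ``test``: "ttest" (two-sided Welch-free two-sample), "wilcoxon" (paired
    signed-rank), "kruskal" or "anova_tukey" (these two use ``groups``).
    Degenerate inputs are skipped with a reason rather than raising.
    """
    if test in ("kruskal", "anova_tukey"):
        groups = [np.asarray(g, dtype=float) for g in (groups or [])]
        groups = [g[~np.isnan(g)] for g in groups]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            return GroupTestResult(test, np.nan, np.nan, skipped="degenerate groups")
        if test == "kruskal":
            try:
                stat, p = stats.kruskal(*groups)
            except ValueError:
                return GroupTestResult(test, np.nan, 1.0, skipped="identical values")
            return GroupTestResult(test, float(stat), float(p))
        stat, p = stats.f_oneway(*groups)
        tukey = stats.tukey_hsd(*groups)
        return GroupTestResult(test, float(stat), float(p), detail=tukey)
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if test == "ttest":
        if len(x) < 2 or len(y) < 2:
            return GroupTestResult(test, np.nan, np.nan, skipped="need >= 2 per group")
        if np.var(x) == 0 and np.var(y) == 0:
            p = 1.0 if x.mean() == y.mean() else 0.0
            direction = "b>a" if y.mean() > x.mean() else ("a>b" if x.mean() > y.mean() else "none")
            return GroupTestResult(test, np.nan, p, direction=direction)
        stat, p = stats.ttest_ind(x, y)
        direction = "a>b" if x.mean() > y.mean() else "b>a"
        return GroupTestResult(test, float(stat), float(p), direction=direction)
    if test == "wilcoxon":
        if len(x) != len(y) or len(x) < 2 or np.allclose(x - y, 0):
            return GroupTestResult(test, np.nan, 1.0, skipped="degenerate pairs")
        stat, p = stats.wilcoxon(x, y)
        direction = "a>b" if np.mean(x - y) > 0 else "b>a"
        return GroupTestResult(test, float(stat), float(p), direction=direction)
    raise ValueError(f"unknown test {test!r}")


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are reported by default)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
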