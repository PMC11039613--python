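"""Functional redundancy and selection/recombination summaries.

The functional redundancy ratio (FRR) of a proteome compartment is
1 - (unique KO labels / total KO annotations): 0 means every annotated
function occurs once, values near 1 mean heavy duplication. Site-level
selection calls (FEL-style) and per-species recombination estimates
(ClonalFrameML-style) arrive as parsed tables from external inference and
are only aggregated here.
"""

from __future__ import annotations

import logging
import warnings
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import compare_groups

logger = logging.getLogger(__name__)

__all__ = [
    "functional_redundancy_ratio",
    "annotation_coverage",
    "compare_frr",
    "classify_gene_selection",
    "selection_summary",
    "recombination_summary",
    "parse_fel_table",
    "parse_cfml_table",
    "TableSchemaError",
]


def functional_redundancy_ratio(ko_labels) -> float:
    """FRR = 1 - unique / total over the annotated labels.

    Unannotated entries (None/NaN/empty) are excluded first; with no
    annotated labels at all the ratio is undefined and NaN is returned.
    """
    labels = [
        l
        for l in ko_labels
        if l is not None and not (isinstance(l, float) and np.isnan(l)) and l != ""
    ]
    if not labels:
        warnings.warn("no annotated proteins: FRR undefined", stacklevel=2)
        return float("nan")
    return 1.0 - len(set(labels)) / len(labels)


def annotation_coverage(ko_labels) -> float:
    """Fraction of proteins carrying a KO annotation (FRR context)."""
    labels = list(ko_labels)
    if not labels:
        return float("nan")
    annotated = sum(
        l is not None and not (isinstance(l, float) and np.isnan(l)) and l != ""
        for l in labels
    )
    return annotated / len(labels)


def compare_frr(frr_table: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon comparisons of per-MAG FRR values across size classes.

    ``frr_table`` needs columns mag_id, size_class, compartment, frr. The
    headline comparison is within the SP compartment across size classes;
    the CP counterpart is reported alongside.
    """
    rows = []
    for comp, sub in frr_table.groupby("compartment"):
        groups = {
            str(sc): grp["frr"].dropna().tolist()
            for sc, grp in sub.groupby("size_class")
        }
        try:
            rep = compare_groups(groups)
        except ValueError:
            continue
        rep.insert(0, "compartment", comp)
        rows.append(rep)
    if not rows:
        raise ValueError("no compartment had two comparable size-class groups")
    return pd.concat(rows, ignore_index=True)


def classify_gene_selection(
    sites: pd.DataFrame, alpha: float = 0.05, invariant: bool = False
) -> str:
    """Gene-level selection call from per-site tests.

    ``positive`` if any positively selected site is significant at
    ``alpha`` (positive takes precedence over negative: a gene with any
    adaptive site counts as adaptive); else ``negative`` if any negative
    site is significant; else ``invariant`` when the caller flags a
    zero-polymorphism alignment; else ``none``.
    """
    if invariant:
        return "invariant"
    if sites.empty:
        return "none"
    sig = sites[sites["p_value"] < alpha]
    if (sig["direction"] == "positive").any():
        return "positive"
    if (sig["direction"] == "negative").any():
        return "negative"
    return "none"


def selection_summary(
    sites: pd.DataFrame,
    gene_meta: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Selection proportions and chi-square homogeneity per size class.

    ``sites``: FEL-style site table (species_id, gene_id, compartment,
    site_index, direction, p_value). ``gene_meta``: one row per gene with
    columns gene_id, size_class, compartment and optional boolean
    ``invariant``. Returns (proportions, negative-sites-per-gene table,
    chi-square report). The chi-square tests, within each size class, the
    2 (compartment) x 3 (positive/negative/other) gene-count table; with
    both compartments and three categories it has 2 degrees of freedom.
    """
    meta = gene_meta.set_index("gene_id")
    calls = {}
    neg_sites = {}
    for gid in meta.index:
        gene_sites = sites[sites["gene_id"] == gid]
        inv = bool(meta["invariant"].get(gid, False)) if "invariant" in meta else False
        calls[gid] = classify_gene_selection(gene_sites, alpha, inv)
        neg_sites[gid] = int(
            ((gene_sites["direction"] == "negative") & (gene_sites["p_value"] < alpha)).sum()
        )
    meta = meta.assign(
        call=pd.Series(calls), n_negative_sites=pd.Series(neg_sites)
    ).reset_index()

    prop_rows = []
    for (sc, comp), grp in meta.groupby(["size_class", "compartment"]):
        n = len(grp)
        if n == 0:
            warnings.warn(f"empty cell ({sc}, {comp})", stacklevel=2)
        prop_rows.append(
            {
                "size_class": sc,
                "compartment": comp,
                "n_genes": n,
                "pct_positive": 100.0 * (grp["call"] == "positive").mean() if n else 0.0,
                "pct_negative": 100.0 * (grp["call"] == "negative").mean() if n else 0.0,
                "pct_invariant": 100.0 * (grp["call"] == "invariant").mean() if n else 0.0,
            }
        )
    proportions = pd.DataFrame(prop_rows)

    chi_rows = []
    meta["category"] = meta["call"].where(
        meta["call"].isin(["positive", "negative"]), "other"
    )
    for sc, grp in meta.groupby("size_class"):
        table = pd.crosstab(grp["compartment"], grp["category"]).reindex(
            columns=["positive", "negative", "other"], fill_value=0
        )
        if table.shape[0] < 2 or (table.to_numpy().sum(axis=0) > 0).sum() < 2:
            continue
        table = table.loc[:, table.sum(axis=0) > 0]
        chi2, p, dof, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        chi_rows.append(
            {"size_class": sc, "chi2": float(chi2), "df": int(dof), "p_value": float(p)}
        )
    chisq = pd.DataFrame(chi_rows, columns=["size_class", "chi2", "df", "p_value"])
    per_gene = meta[
        ["gene_id", "size_class", "compartment", "call", "n_negative_sites"]
    ]
    return proportions, per_gene, chisq


def recombination_summary(estimates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Medians and cross-size-class tests of recombination statistics.

    ``estimates`` columns: species_id, size_class, compartment, r_over_m,
    nu, delta. Returns (medians table with per-species unity flags,
    Kruskal-Wallis report comparing size classes within each compartment
    for r/m and nu). With a single size class the tests are skipped.
    """
    if estimates.empty:
        raise ValueError("no recombination estimates supplied")
    est = estimates.copy()
    est["rm_exceeds_unity"] = est["r_over_m"] > 1.0

    med = (
        est.groupby(["size_class", "compartment"])[["r_over_m", "nu", "delta"]]
        .median()
        .reset_index()
    )
    tests = []
    for comp, sub in est.groupby("compartment"):
        by_class = {
            sc: grp for sc, grp in sub.groupby("size_class") if len(grp) >= 1
        }
        if len(by_class) < 2:
            continue
        for stat in ("r_over_m", "nu"):
            samples = [grp[stat].dropna().to_numpy() for grp in by_class.values()]
            if any(len(s) < 2 for s in samples):
                continue
            if len(np.unique(np.concatenate(samples))) < 2:
                continue  # constant statistic: no rank test possible
            h, p = sps.kruskal(*samples)
            tests.append(
                {
                    "compartment": comp,
                    "statistic": stat,
                    "test": "kruskal_wallis",
                    "H": float(h),
                    "p_value": float(p),
                }
            )
    test_df = pd.DataFrame(
        tests, columns=["compartment", "statistic", "test", "H", "p_value"]
    )
    med = med.merge(
        est.groupby(["size_class", "compartment"])["rm_exceeds_unity"]
        .mean()
        .rename("fraction_rm_above_unity")
        .reset_index(),
        on=["size_class", "compartment"],
    )
    return med, test_df


class TableSchemaError(ValueError):
    """An external-tool table does not match its documented schema."""


_FEL_COLUMNS = ["species_id", "gene_id", "compartment", "site_index", "direction", "p_value"]
_CFML_COLUMNS = ["species_id", "compartment", "r_over_m", "nu", "delta"]


def parse_fel_table(path_or_buf) -> pd.DataFrame:
    """Read a FEL-style per-site selection TSV.

    Schema: species_id, gene_id, compartment (SP|CP), site_index (>= 1),
    direction (positive|negative), p_value in [0, 1]. Rows with out-of-range
    p-values or site indices are dropped and logged; unknown directions are
    a schema error.
    """
    try:
        df = pd.read_csv(path_or_buf, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_FEL_COLUMNS)
    missing = [c for c in _FEL_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"selection table lacks column(s): {missing}")
    bad_dir = ~df["direction"].isin(["positive", "negative"])
    if bad_dir.any():
        raise TableSchemaError(
            f"unknown direction value(s): {sorted(df.loc[bad_dir, 'direction'].unique())}"
        )
    ok = df["p_value"].between(0.0, 1.0) & (df["site_index"] >= 1)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("selection table: dropped %d invalid row(s)", dropped)
    return df[ok].reset_index(drop=True)[_FEL_COLUMNS]


def parse_cfml_table(path_or_buf) -> pd.DataFrame:
    """Read a ClonalFrameML-style per-species recombination TSV.

    Schema: species_id, compartment (SP|CP), r_over_m, nu, delta, all
    non-negative. The source tooling names both "average length of imports"
    and import divergence nu; both nu and delta (mean import length, bp)
    are carried so either reading is available.
    """
    try:
        df = pd.read_csv(path_or_buf, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_CFML_COLUMNS)
    missing = [c for c in _CFML_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"recombination table lacks column(s): {missing}")
    for col in ("r_over_m", "nu", "delta"):
        bad = df[col] < 0
        if bad.any():
            raise TableSchemaError(f"negative values in column {col!r}")
    return df[_CFML_COLUMNS].copy()
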