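"""Group-wise comparisons of positional hydrogen-bond content.

Three kinds of grouping are supported:

- by CDS position within operons (first CDS vs. internal CDSs; nonparametric
  pairwise Wilcoxon rank-sum and joint Kruskal-Wallis tests per region),
- by expression strata (CDSs in the top/bottom percentile of transcript
  abundance in *every* experiment of a compendium),
- correlation analyses among positional metric profiles (Spearman network,
  per-region Pearson/Spearman against e.g. an mRNA-structure profile).

Multiple-testing correction uses the Benjamini-Yekutieli procedure, which
is valid under arbitrary dependence of the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .genetic_code import STANDARD_TABLE
from .orfeome import CodonMatrix, Orfeome, encode_cds
from .profiles import PositionalProfile, positional_profile

__all__ = [
    "OperonTable",
    "read_operon_table",
    "read_expression_table",
    "operon_comparison",
    "expression_strata",
    "strata_profiles",
    "metric_correlation_network",
    "region_correlation",
]


@dataclass
class OperonTable:
    """cds_id -> (operon_id, 1-based position within the operon).

    Only operons with >= 2 CDSs are retained; positions within an operon
    must be consecutive from 1.
    """

    table: pd.DataFrame  # columns: cds_id, operon_id, position

    def __post_init__(self):
        df = self.table
        required = {"cds_id", "operon_id", "position"}
        if not required.issubset(df.columns):
            raise ValueError(f"operon table needs columns {sorted(required)}")
        sizes = df.groupby("operon_id")["cds_id"].size()
        keep = sizes[sizes >= 2].index
        df = df[df["operon_id"].isin(keep)].copy()
        for op, grp in df.groupby("operon_id"):
            pos = sorted(grp["position"])
            if pos != list(range(1, len(pos) + 1)):
                raise ValueError(f"operon {op!r}: positions not consecutive from 1")
        self.table = df.reset_index(drop=True)

    def groups(self, max_position: int = 3) -> dict[int, list[str]]:
        """CDS ids grouped by within-operon position 1..max_position."""
        out = {}
        for p in range(1, max_position + 1):
            ids = self.table.loc[self.table["position"] == p, "cds_id"].tolist()
            if ids:
                out[p] = ids
        return out


def read_operon_table(path) -> OperonTable:
    return OperonTable(pd.read_csv(path, sep="\t", comment="#"))


def read_expression_table(path) -> pd.DataFrame:
    """Long TSV (cds_id, experiment, rpkm) -> wide DataFrame cds x experiment."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"cds_id", "experiment", "rpkm"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    wide = df.pivot(index="cds_id", columns="experiment", values="rpkm")
    if wide.isna().any().any():
        raise ValueError("expression table does not cover the same CDSs in all experiments")
    if (wide < 0).any().any():
        raise ValueError("negative abundance in expression table")
    return wide


def _region_means(matrix: CodonMatrix, orfeome: Orfeome | None):
    """Per-CDS mean hbond values for each comparison region.

    Regions: five 20-codon windows across the analysis window, the whole
    window, and (when full sequences are available) the entire CDS.
    Labels use original codon positions (start codon = position 1).
    """
    hb = STANDARD_TABLE.hbond_by_index[matrix.codes].astype(float)
    npos = matrix.n_positions
    regions: dict[str, pd.Series] = {}
    step = 20
    for lo in range(0, npos - npos % step, step):
        p_lo, p_hi = lo + matrix.position_offset, lo + step - 1 + matrix.position_offset
        regions[f"P{p_lo}-P{p_hi}"] = pd.Series(
            hb[:, lo : lo + step].mean(axis=1), index=matrix.cds_ids
        )
    regions[f"P{matrix.position_offset}-P{npos + matrix.position_offset - 1}"] = pd.Series(
        hb.mean(axis=1), index=matrix.cds_ids
    )
    if orfeome is not None:
        full = {}
        for cid, seq in orfeome:
            codes = encode_cds(seq, ambiguous={})
            std = codes[codes < 64]
            full[cid] = float(STANDARD_TABLE.hbond_by_index[std].mean())
        regions["full"] = pd.Series(full)
    return regions


def operon_comparison(
    matrix: CodonMatrix,
    operons: OperonTable,
    orfeome: Orfeome | None = None,
    max_cds_position: int = 3,
) -> dict[str, pd.DataFrame]:
    """Compare hydrogen bonding of CDSs by their position within operons.

    Returns ``{"pairwise": ..., "groupwise": ...}``: two-sided Wilcoxon
    rank-sum tests for every group pair in every region (BY-adjusted
    across the whole report) and a Kruskal-Wallis test per region.
    Groups with < 2 CDSs are skipped and flagged in the output.
    """
    known = set(matrix.cds_ids)
    missing = [c for c in operons.table["cds_id"] if c not in known]
    if missing:
        raise ValueError(f"operon table references unknown cds_id {missing[0]!r}")
    groups = operons.groups(max_cds_position)
    regions = _region_means(matrix, orfeome)

    pair_rows, group_rows = [], []
    for region, values in regions.items():
        samples = {
            p: values.reindex(ids).dropna().to_numpy()
            for p, ids in groups.items()
        }
        usable = {p: v for p, v in samples.items() if v.size >= 2}
        skipped = sorted(set(samples) - set(usable))
        if len(usable) >= 2:
            kw = stats.kruskal(*usable.values())
            group_rows.append(
                {
                    "region": region,
                    "groups": ",".join(str(p) for p in usable),
                    "statistic": kw.statistic,
                    "p": kw.pvalue,
                    "skipped_groups": ",".join(str(p) for p in skipped),
                }
            )
        ps = sorted(usable)
        for i, a in enumerate(ps):
            for b in ps[i + 1 :]:
                mw = stats.mannwhitneyu(usable[a], usable[b], alternative="two-sided")
                pair_rows.append(
                    {
                        "region": region,
                        "group_a": a,
                        "group_b": b,
                        "n_a": usable[a].size,
                        "n_b": usable[b].size,
                        "statistic": mw.statistic,
                        "p_raw": mw.pvalue,
                    }
                )
    pairwise = pd.DataFrame(pair_rows)
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p_raw"], method="fdr_by")[1]
    groupwise = pd.DataFrame(group_rows)
    return {"pairwise": pairwise, "groupwise": groupwise}


def expression_strata(
    expr: pd.DataFrame, high_pct: float, low_pct: float
) -> tuple[list[str], list[str]]:
    """CDSs in the top ``high_pct``% / bottom ``low_pct``% in every experiment.

    ``expr`` is a wide DataFrame (cds x experiment, RPKM).  Ranking is by
    abundance, ties broken by stable input order.  Documented preset pairs:
    (5,13), (10,18), (15,23), (20,26), (25,30), (30,35); the looser bottom
    cut yields comparison sets of similar size.
    """
    for pct in (high_pct, low_pct):
        if not 0 < pct < 100:
            raise ValueError("percentages must lie in (0, 100)")
    n = len(expr)
    k_hi = max(int(np.floor(n * high_pct / 100 + 1e-9)), 0)
    k_lo = max(int(np.floor(n * low_pct / 100 + 1e-9)), 0)
    high: set | None = None
    low: set | None = None
    for col in expr.columns:
        order = expr[col].to_numpy()
        idx = np.argsort(-order, kind="stable")
        ids = expr.index.to_numpy()
        top = set(ids[idx[:k_hi]])
        idx_lo = np.argsort(order, kind="stable")
        bottom = set(ids[idx_lo[:k_lo]])
        high = top if high is None else high & top
        low = bottom if low is None else low & bottom
    return sorted(high or ()), sorted(low or ())


def strata_profiles(
    matrix: CodonMatrix,
    groups: dict[str, list[str]],
    span: float = 0.75,
    n_boot: int = 1000,
    seed=0,
) -> dict[str, tuple[PositionalProfile, np.ndarray]]:
    """Positional hbond profile plus a LOESS-smoothed curve per CDS group."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = {cid: i for i, cid in enumerate(matrix.cds_ids)}
    out = {}
    for label, ids in groups.items():
        rows = [index[c] for c in ids if c in index]
        if len(rows) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 CDSs in the matrix")
        sub = CodonMatrix([matrix.cds_ids[i] for i in rows], matrix.codes[rows], matrix.position_offset)
        prof = positional_profile(
            sub,
            STANDARD_TABLE.hbond_by_index.astype(float),
            n_boot=n_boot,
            seed=rng,
            metric_name=f"hbond[{label}]",
        )
        smooth = lowess(prof.mean, prof.positions, frac=span, return_sorted=False)
        out[label] = (prof, smooth)
    return out


def metric_correlation_network(
    profiles: dict[str, PositionalProfile],
    method: str = "spearman",
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, nx.Graph]:
    """All-pairs rank correlation among positional metric profiles.

    Profiles must share identical positions (>= 3).  Returns the edge list
    (rho, raw and BY-adjusted p, significance at ``alpha``) and a graph
    whose edges are the significant associations.
    """
    names = sorted(profiles)
    if len(names) < 2:
        raise ValueError("need at least two profiles")
    pos0 = profiles[names[0]].positions
    if pos0.size < 3:
        raise ValueError("need at least 3 shared positions")
    for nm in names[1:]:
        if not np.array_equal(profiles[nm].positions, pos0):
            raise ValueError(f"profile {nm!r} covers different positions")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = corr(profiles[a].mean, profiles[b].mean)
            rows.append({"metric_a": a, "metric_b": b, "rho": float(r.statistic), "p_raw": float(r.pvalue)})
    edges = pd.DataFrame(rows)
    edges["p_adj"] = multipletests(edges["p_raw"], method="fdr_by")[1]
    edges["significant"] = edges["p_adj"] < alpha
    g = nx.Graph()
    g.add_nodes_from(names)
    for _, row in edges[edges["significant"]].iterrows():
        g.add_edge(row["metric_a"], row["metric_b"], rho=row["rho"], p_adj=row["p_adj"])
    return edges, g


def region_correlation(
    profile_a: PositionalProfile,
    profile_b: PositionalProfile,
    regions: list[tuple[int, int]] = ((2, 120), (2, 60), (2, 30)),
) -> pd.DataFrame:
    """Pearson and Spearman correlation of two profiles per position region.

    Regions are (start, end) in original codon positions, inclusive.
    """
    if not np.array_equal(profile_a.positions, profile_b.positions):
        raise ValueError("profiles cover different positions")
    pos = profile_a.positions
    rows = []
    for lo, hi in regions:
        mask = (pos >= lo) & (pos <= hi)
        if mask.sum() < 3:
            raise ValueError(f"region P{lo}-P{hi}: fewer than 3 shared positions")
        a, b = profile_a.mean[mask], profile_b.mean[mask]
        pr = stats.pearsonr(a, b)
        sr = stats.spearmanr(a, b)
        rows.append(
            {
                "region": f"P{lo}-P{hi}",
                "pearson_r": float(pr.statistic),
                "pearson_p": float(pr.pvalue),
                "spearman_rho": float(sr.statistic),
                "spearman_p": float(sr.pvalue),
            }
        )
    return pd.DataFrame(rows)
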