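"""Change%-of-control response profiles, clustering and variance partitioning.

The unit of tolerance typing is the change percentage: a genotype's stress
cell mean expressed as a percentage of its control cell mean (100 = no
change).  Genotypes (or traits) are grouped by agglomerative hierarchical
clustering of these profiles; group labels are renumbered by descending
group-mean GY change% so that the most affected group is always the highest
numbered one, making group identities deterministic.

Group profiles re-express each group's mean change% as a proportion of the
unweighted grand-mean change% over all genotypes (100 = panel average), and
compact letter displays from Tukey HSD pairwise tests mark group separation
at the chosen alpha.  A closed-form balanced two-way fixed-effects ANOVA
partitions the total sum of squares into treatment, genotype, interaction
and residual shares (SS%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .exceptions import BalanceError, PhenomicsWarning
from .tables import PhenotypeTable
from .traits import TREATMENTS


# ---------------------------------------------------------------------------
# change% matrices


def change_percent_matrix(
    table: PhenotypeTable, treatment: str, traits=None
) -> pd.DataFrame:
    """Traits x genotypes matrix of 100 * stress mean / control mean.

    Cells whose control mean is zero are recorded missing with a warning.
    The frame carries the treatment tag in ``.attrs["treatment"]``.
    """
    if treatment == "C":
        raise ValueError("change% is defined against control; pass 'Ds' or 'Dd'")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    use = traits if traits is not None else table.traits
    rows = {}
    n_zero = 0
    for tr in use:
        means = table.cell_means(tr)
        if treatment not in means.columns or "C" not in means.columns:
            raise ValueError(f"treatment {treatment} or control absent for {tr}")
        ctrl = means["C"].to_numpy(dtype=float)
        strs = means[treatment].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * strs / ctrl
        zero = ctrl == 0
        n_zero += int(zero.sum())
        pct[zero] = np.nan
        rows[tr] = pd.Series(pct, index=means.index)
    if n_zero:
        warnings.warn(
            f"{n_zero} control-zero cell(s) recorded missing in change% matrix",
            PhenomicsWarning, stacklevel=2,
        )
    mat = pd.DataFrame(rows).T
    mat = mat.loc[list(use)]
    mat.attrs["treatment"] = treatment
    return mat


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaves: list
    labels: pd.Series  # leaf -> group number (1..k)
    axis: str

    def to_newick(self) -> str:
        """Newick string with leaf names and merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist):
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{parent_dist - 0.0:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{parent_dist - node.dist:.6g}"

        root = tree
        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


def cluster_axis(
    matrix: pd.DataFrame,
    axis: str = "genotypes",
    k: int = 3,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of one axis of a change% matrix.

    Defaults (Euclidean distance, complete linkage, raw change% values) match
    common heatmap tooling.  Rows/columns containing missing values on the
    clustered axis are dropped with a warning.  Cut labels are renumbered so
    group 1 has the highest mean GY change% (least affected) and group k the
    lowest, when GY is among the traits; otherwise by overall mean change%.
    """
    if axis not in ("genotypes", "traits"):
        raise ValueError("axis must be 'genotypes' or 'traits'")
    data = matrix.T if axis == "genotypes" else matrix
    incomplete = data.index[data.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} {axis} with missing change% values: "
            f"{list(incomplete)[:5]}",
            PhenomicsWarning, stacklevel=2,
        )
        data = data.drop(index=incomplete)
    if k > len(data):
        raise ValueError(f"k={k} exceeds axis length {len(data)}")
    Z = hierarchy.linkage(data.to_numpy(), method=linkage, metric=distance)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=data.index, name="group")

    # deterministic numbering: descending group-mean GY change%
    if axis == "genotypes":
        score_src = matrix.loc["GY"] if "GY" in matrix.index else matrix.mean(axis=0)
        key = labels.groupby(labels).apply(
            lambda idx: score_src[idx.index].mean()
        )
    else:
        key = labels.groupby(labels).apply(
            lambda idx: matrix.loc[idx.index].mean(axis=1).mean()
        )
    order = key.sort_values(ascending=False).index
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = labels.map(remap).astype(int)
    return ClusterResult(linkage=Z, leaves=list(data.index), labels=labels, axis=axis)


# ---------------------------------------------------------------------------
# group profiles


def group_profile(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-group, per-trait change% as a proportion of the grand mean.

    Grand mean is the unweighted mean over all labeled genotypes of the
    change% values; with a single group every profile value is 100.  Empty
    groups are excluded with a warning.  Group member lists live in
    ``.attrs["members"]``.
    """
    cols = [g for g in matrix.columns if g in labels.index]
    missing = set(matrix.columns) - set(cols)
    if missing:
        raise ValueError(f"labels do not cover genotype(s): {sorted(missing)}")
    grand = matrix[cols].mean(axis=1)
    profiles = {}
    members = {}
    for grp in sorted(labels.unique()):
        idx = [g for g in cols if labels[g] == grp]
        if not idx:
            warnings.warn(f"group {grp} is empty; excluded", PhenomicsWarning,
                          stacklevel=2)
            continue
        profiles[grp] = 100.0 * matrix[idx].mean(axis=1) / grand
        members[grp] = idx
    out = pd.DataFrame(profiles)
    out.attrs["members"] = members
    return out


def group_separation_letters(
    values: pd.Series, labels: pd.Series, alpha: float = 0.05
) -> dict:
    """Compact letter display from one-way ANOVA + Tukey HSD.

    Groups sharing a letter are not significantly different at ``alpha``.
    Letters are assigned to the maximal cliques of the
    not-significantly-different graph, ordered by descending group mean.
    Degenerate input (all values identical) yields a single shared letter.
    """
    groups = sorted(labels.unique())
    samples = {g: values[labels[labels == g].index].dropna().to_numpy()
               for g in groups}
    small = [g for g, s in samples.items() if len(s) < 2]
    if len(groups) < 2 or small:
        raise ValueError(
            "letter display needs >= 2 groups with >= 2 members each"
        )
    pooled = np.concatenate(list(samples.values()))
    if np.ptp(pooled) == 0:
        return {g: "a" for g in groups}

    res = stats.tukey_hsd(*[samples[g] for g in groups])
    nsd = nx.Graph()
    nsd.add_nodes_from(range(len(groups)))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if res.pvalue[i, j] >= alpha:
                nsd.add_edge(i, j)

    means = {i: samples[g].mean() for i, g in enumerate(groups)}
    cliques = list(nx.find_cliques(nsd))
    cliques.sort(key=lambda c: -max(means[i] for i in c))
    letter_of = {i: [] for i in range(len(groups))}
    for li, clique in enumerate(cliques):
        ch = chr(ord("a") + li)
        for i in clique:
            letter_of[i].append(ch)
    return {g: "".join(sorted(letter_of[i])) for i, g in enumerate(groups)}


# ---------------------------------------------------------------------------
# balanced two-way ANOVA SS%


@dataclass
class AnovaPartition:
    trait: str
    ss: dict          # factor -> sum of squares
    ss_pct: dict      # factor -> SS as % of total
    df: dict
    f: dict           # factor -> F statistic vs MS_error
    p: dict
    stars: dict       # factor -> '', '*', '**', '***'

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in ("treatment", "genotype", "interaction", "residual"):
            rows.append({
                "factor": f, "df": self.df[f], "SS": self.ss[f],
                "SS_pct": self.ss_pct[f],
                "F": self.f.get(f, np.nan), "p": self.p.get(f, np.nan),
                "stars": self.stars.get(f, ""),
            })
        return pd.DataFrame(rows)


def _stars(p: float) -> str:
    return "***" if p <= 0.001 else "**" if p <= 0.01 else "*" if p <= 0.05 else ""


def balanced_two_way_ss(values: np.ndarray) -> dict:
    """Sums of squares of a balanced genotype x treatment x replicate array.

    ``values`` has shape (n_genotypes, n_treatments, n_reps).  Returns SS and
    df for genotype, treatment, interaction, residual and total.
    """
    y = np.asarray(values, dtype=float)
    n, t, r = y.shape
    grand = y.mean()
    cell = y.mean(axis=2)
    gmean = y.mean(axis=(1, 2))
    tmean = y.mean(axis=(0, 2))
    ss_g = t * r * float(((gmean - grand) ** 2).sum())
    ss_t = n * r * float(((tmean - grand) ** 2).sum())
    ss_int = r * float(
        ((cell - gmean[:, None] - tmean[None, :] + grand) ** 2).sum()
    )
    ss_err = float(((y - cell[:, :, None]) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    return {
        "ss": {"genotype": ss_g, "treatment": ss_t, "interaction": ss_int,
               "residual": ss_err, "total": ss_tot},
        "df": {"genotype": n - 1, "treatment": t - 1,
               "interaction": (n - 1) * (t - 1), "residual": n * t * (r - 1),
               "total": n * t * r - 1},
        "shape": (n, t, r),
    }


def _balanced_array(table: PhenotypeTable, trait: str) -> tuple[np.ndarray, list, list, int]:
    d = table.data[(table.data["trait"] == trait)].dropna(subset=["value"])
    genos = sorted(d["genotype"].unique())
    treats = [t for t in TREATMENTS if t in set(d["treatment"])]
    counts = d.groupby(["genotype", "treatment"]).size()
    if counts.empty:
        raise BalanceError(f"no data for trait {trait}")
    r = int(counts.iloc[0])
    if counts.nunique() != 1 or len(counts) != len(genos) * len(treats):
        raise BalanceError(
            f"unbalanced layout for {trait}; validate balance before the "
            "two-way analysis"
        )
    arr = np.empty((len(genos), len(treats), r))
    piv = d.sort_values("replicate").groupby(["genotype", "treatment"])["value"]
    for i, g in enumerate(genos):
        for j, t in enumerate(treats):
            arr[i, j, :] = piv.get_group((g, t)).to_numpy()
    return arr, genos, treats, r


def anova_ss_partition(
    table: PhenotypeTable, trait: str, row_type: str | None = None
) -> AnovaPartition:
    """Fixed-effects two-way ANOVA SS% for one trait (optionally one row type).

    SS% = SS_factor / SS_total x 100; F-tests against the residual mean
    square give significance stars at 0.05 / 0.01 / 0.001.
    """
    sub = table.subset(row_type=row_type) if row_type else table
    arr, genos, treats, r = _balanced_array(sub, trait)
    if len(genos) < 2 or len(treats) < 2 or r < 2:
        raise BalanceError("need >= 2 genotypes, >= 2 treatments, >= 2 replicates")
    res = balanced_two_way_ss(arr)
    ss, df = res["ss"], res["df"]
    ms_err = ss["residual"] / df["residual"]
    f, p, stars_ = {}, {}, {}
    for factor in ("treatment", "genotype", "interaction"):
        if ms_err == 0:
            f[factor], p[factor] = np.inf if ss[factor] > 0 else 0.0, 0.0
        else:
            f[factor] = (ss[factor] / df[factor]) / ms_err
            p[factor] = float(stats.f.sf(f[factor], df[factor], df["residual"]))
        stars_[factor] = _stars(p[factor])
    ss_pct = {k: 100.0 * ss[k] / ss["total"] for k in
              ("treatment", "genotype", "interaction", "residual")}
    return AnovaPartition(trait=trait, ss=ss, ss_pct=ss_pct, df=df,
                          f=f, p=p, stars=stars_)
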