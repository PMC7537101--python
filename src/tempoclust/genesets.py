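"""Gene-set over-representation, cross-list overlap testing and aggregation.

Over-representation uses the upper-tail hypergeometric test with
Benjamini-Hochberg adjustment across the sets tested for each query —
the significance contract is an adjusted p below 0.05. Cross-study overlap
testing treats each external gene list as a gene-set entry (the custom-GMT
construction) and runs the same machinery. Exclusive intersection counts
(as drawn by UpSet-style plots) and replicate-wise pathway-level expression
aggregation round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dge import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_overrep",
    "enrich",
    "crossstudy_overlap",
    "upset_counts",
    "aggregate_pathway",
]


class GMTFormatError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> (description, member genes).

    Members are deduplicated preserving first appearance. ``universe`` is an
    optional explicit background gene list; when absent, callers supply one.
    """

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, list[str]]] = {}
        for name, (desc, members) in self.sets.items():
            if not name:
                raise GMTFormatError("empty set name")
            deduped = list(dict.fromkeys(m for m in members if m))
            if len(deduped) < len([m for m in members if m is not None]):
                pass  # silent dedup, mirrors GMT semantics
            clean[name] = (desc, deduped)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, description: str, members: list[str]) -> None:
        if name in self.sets:
            raise GMTFormatError(f"duplicate set name {name!r}")
        self.sets[name] = (description, list(dict.fromkeys(members)))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a standard GMT file: name TAB description TAB gene1 TAB gene2...

    Malformed lines (fewer than 3 fields) and duplicate set names are
    rejected with the offending line number.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    nonempty = [(i, ln) for i, ln in enumerate(lines, start=1) if ln.strip()]
    if not nonempty:
        raise GMTFormatError(f"{path}: empty GMT file")
    for lineno, ln in nonempty:
        fields = ln.split("\t")
        if len(fields) < 3:
            raise GMTFormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        name, desc, *members = fields
        if name in sets:
            raise GMTFormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def hypergeom_overrep(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value.

    Probability of drawing ``k`` or more members of a ``K``-gene set when
    sampling ``n`` genes without replacement from a universe of ``N``.
    """
    if not (0 <= k <= min(K, n) <= N) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


ENRICHMENT_COLUMNS = [
    "query_name",
    "set_name",
    "overlap_k",
    "set_size_K",
    "query_size_n",
    "universe_N",
    "pvalue",
    "adjp",
    "significant",
    "overlap_genes",
]


def enrich(
    queries: dict[str, list[str]],
    gmt: GeneSetCollection,
    universe: list[str] | None = None,
    alpha: float = 0.05,
    case_fold: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each query list in each gene set.

    Sets are intersected with the universe before testing; BH adjustment is
    applied across all sets within each query. Gene matching is exact-string,
    optionally case-folded.
    """
    if universe is None:
        universe = gmt.universe
    if not universe:
        raise ValueError("empty or missing universe")

    def norm(genes) -> list[str]:
        return list(dict.fromkeys(g.casefold() if case_fold else g for g in genes))

    uni = set(norm(universe))
    N = len(uni)
    rows = []
    for qname, qgenes in queries.items():
        q = set(norm(qgenes))
        if not q:
            raise ValueError(f"query {qname!r} is empty")
        stray = q - uni
        if stray:
            raise ValueError(
                f"query {qname!r} has {len(stray)} genes outside the universe "
                f"(e.g. {sorted(stray)[:3]})"
            )
        n = len(q)
        pvals = []
        qrows = []
        for sname in gmt.names():
            members = set(norm(gmt.members(sname))) & uni
            K = len(members)
            overlap = sorted(q & members)
            k = len(overlap)
            p = hypergeom_overrep(k, K, n, N) if K else 1.0
            pvals.append(p)
            qrows.append(
                {
                    "query_name": qname,
                    "set_name": sname,
                    "overlap_k": k,
                    "set_size_K": K,
                    "query_size_n": n,
                    "universe_N": N,
                    "pvalue": p,
                    "overlap_genes": ",".join(overlap),
                }
            )
        adj = bh_adjust(np.array(pvals))
        for r, a in zip(qrows, adj):
            r["adjp"] = float(a)
            r["significant"] = bool(a < alpha)
        rows.extend(qrows)
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


def crossstudy_overlap(
    lists: dict[str, list[str]],
    universe: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise overlap significance between named gene lists.

    Each list is tested as a query against every *other* list treated as a
    gene-set entry (the custom-GMT construction used when comparing
    up/downregulated lists across studies and timepoints), hypergeometric
    with BH adjustment within each query.
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    uni = set(universe)
    for name, genes in lists.items():
        stray = set(genes) - uni
        if stray:
            raise ValueError(f"list {name!r} not contained in universe ({len(stray)} strays)")
    frames = []
    for qname in lists:
        gmt = GeneSetCollection(
            sets={
                sname: (f"gene list {sname}", list(genes))
                for sname, genes in lists.items()
                if sname != qname
            }
        )
        frames.append(enrich({qname: lists[qname]}, gmt, universe=universe, alpha=alpha))
    return pd.concat(frames, ignore_index=True)


def upset_counts(lists: dict[str, list[str]]) -> pd.DataFrame:
    """Exclusive intersection counts over every combination of the lists.

    Returns one row per nonempty combination with a positive count of
    elements belonging to *exactly* the lists in the combination, ordered by
    degree then by count descending (then combination label for stability),
    plus per-list totals in the ``total`` rows' companion attribute columns.
    Exclusive counts over all combinations sum to the size of the union.
    """
    if not lists:
        raise ValueError("need at least one list")
    names = list(lists)
    membership: dict[str, frozenset[str]] = {}
    for elem in set().union(*(set(v) for v in lists.values())):
        membership[elem] = frozenset(n for n in names if elem in set(lists[n]))
    combos: dict[frozenset[str], int] = {}
    for combo in membership.values():
        combos[combo] = combos.get(combo, 0) + 1
    rows = [
        {
            "combination": "&".join(n for n in names if n in combo),
            "degree": len(combo),
            "exclusive_count": count,
        }
        for combo, count in combos.items()
    ]
    rows.sort(key=lambda r: (r["degree"], -r["exclusive_count"], r["combination"]))
    df = pd.DataFrame(rows, columns=["combination", "degree", "exclusive_count"])
    df.attrs["totals"] = {n: len(set(lists[n])) for n in names}
    return df


def aggregate_pathway(
    vst: pd.DataFrame,
    design: pd.DataFrame,
    pathways: dict[str, list[str]],
) -> pd.DataFrame:
    """Replicate-wise mean expression over each pathway's genes.

    For every sample, the arithmetic mean of the VST values of the pathway's
    genes, keyed by pathway x genotype x timepoint x replicate. Pathway
    members absent from the matrix are dropped with a warning; a pathway with
    no matched genes is an error.
    """
    rows = []
    for pname, genes in pathways.items():
        present = [g for g in dict.fromkeys(genes) if g in vst.index]
        missing = len(dict.fromkeys(genes)) - len(present)
        if not present:
            raise ValueError(f"pathway {pname!r} has no genes in the expression matrix")
        if missing:
            warnings.warn(f"pathway {pname!r}: dropping {missing} absent gene(s)")
        means = vst.loc[present].mean(axis=0)
        for sid, val in means.items():
            d = design.loc[sid]
            rows.append(
                {
                    "pathway": pname,
                    "genotype": d["genotype"],
                    "timepoint": d["timepoint"],
                    "replicate": d["replicate"],
                    "sample_id": sid,
                    "mean_vst": float(val),
                }
            )
    return pd.DataFrame(
        rows, columns=["pathway", "genotype", "timepoint", "replicate", "sample_id", "mean_vst"]
    )
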