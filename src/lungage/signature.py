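"""Consensus aging signatures from per-cell-type DEG calls.

A gene joins the up (down) signature when it is called up (down) in at
least ``min_celltypes`` cell types. Membership is tracked in a boolean
genes x cell-types matrix per direction, from which upset-style exact
intersection sets are computed. Genes qualifying in both directions (up in
some cell types, down in others) are excluded from both signatures and
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class MembershipMatrix:
    """Boolean genes x cell_types membership for one direction."""

    direction: str
    table: pd.DataFrame  # genes x cell_types, bool

    def intersection_sets(self) -> pd.DataFrame:
        """Exact upset decomposition: one row per observed full membership
        pattern, with its gene list, size, and cell-type count (the color
        dimension of an upset plot)."""
        if self.table.empty:
            return pd.DataFrame(columns=["pattern", "genes", "size", "n_celltypes"])
        patterns: dict[tuple[str, ...], list[str]] = {}
        for gene, row in self.table.iterrows():
            pat = tuple(sorted(self.table.columns[row.to_numpy()]))
            patterns.setdefault(pat, []).append(gene)
        rows = [
            {"pattern": pat, "genes": sorted(gs), "size": len(gs), "n_celltypes": len(pat)}
            for pat, gs in patterns.items()
        ]
        out = pd.DataFrame(rows).sort_values(
            ["size", "n_celltypes"], ascending=[False, False], kind="stable"
        )
        return out.reset_index(drop=True)

    def support_counts(self) -> pd.Series:
        """Number of cell types supporting each gene."""
        return self.table.sum(axis=1)


@dataclass
class SignatureSet:
    name: str
    up_genes: list[str]
    down_genes: list[str]
    min_celltypes: int
    provenance: str = ""
    conflicts: list[str] = field(default_factory=list)

    def genes(self, subset: str = "all") -> list[str]:
        if subset == "up":
            return list(self.up_genes)
        if subset == "down":
            return list(self.down_genes)
        if subset == "all":
            seen = set()
            out = []
            for g in self.up_genes + self.down_genes:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
            return out
        raise ValueError(f"unknown subset {subset!r}")


def build_membership(degs: pd.DataFrame, direction: str) -> MembershipMatrix:
    """Genes x cell-types boolean matrix of significant calls, one direction.

    Only genes significant in at least one cell type appear as rows; only
    tested cell types appear as columns.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    celltypes = sorted(degs["cell_type"].unique())
    hits = degs.loc[degs["direction"] == direction, ["gene", "cell_type"]]
    if hits.empty:
        import warnings

        warnings.warn(f"no significant {direction} genes in any cell type")
        return MembershipMatrix(direction, pd.DataFrame(columns=celltypes, dtype=bool))
    mat = (
        hits.assign(v=True)
        .pivot_table(index="gene", columns="cell_type", values="v", aggfunc="any", fill_value=False)
        .reindex(columns=celltypes, fill_value=False)
        .astype(bool)
        .sort_index()
    )
    return MembershipMatrix(direction, mat)


def max_sharing(membership: MembershipMatrix) -> int:
    """Largest number of cell types any one gene is significant in."""
    if membership.table.empty:
        return 0
    return int(membership.table.sum(axis=1).max())


def _ordered(genes: set[str], support: pd.Series) -> list[str]:
    # descending support, then lexicographic — deterministic output order
    return sorted(genes, key=lambda g: (-int(support[g]), g))


def consensus_signature(
    membership_up: MembershipMatrix,
    membership_down: MembershipMatrix,
    min_celltypes: int = 2,
    name: str = "LungAge",
    provenance: str = "",
) -> SignatureSet:
    """Signature = genes significant in >= min_celltypes cell types per
    direction. Genes significant in both directions anywhere (up in one
    cell type, down in another) are directionally ambiguous and are always
    dropped from both lists, regardless of threshold, and listed in
    ``conflicts``; this keeps the signature monotone in ``min_celltypes``."""
    if min_celltypes < 1:
        raise ValueError("min_celltypes must be at least 1")
    sup_up = membership_up.support_counts()
    sup_down = membership_down.support_counts()
    conflicts = sorted(set(sup_up.index[sup_up >= 1]) & set(sup_down.index[sup_down >= 1]))
    up = set(sup_up.index[sup_up >= min_celltypes]) - set(conflicts)
    down = set(sup_down.index[sup_down >= min_celltypes]) - set(conflicts)
    return SignatureSet(
        name=name,
        up_genes=_ordered(up, sup_up),
        down_genes=_ordered(down, sup_down),
        min_celltypes=min_celltypes,
        provenance=provenance,
        conflicts=conflicts,
    )


def upset_summary(membership: MembershipMatrix) -> dict:
    """JSON-ready upset accounting for one direction."""
    inter = membership.intersection_sets()
    return {
        "direction": membership.direction,
        "n_genes": int(membership.table.shape[0]),
        "max_sharing": max_sharing(membership),
        "patterns": [
            {
                "cell_types": list(r["pattern"]),
                "size": int(r["size"]),
                "n_celltypes": int(r["n_celltypes"]),
                "genes": r["genes"],
            }
            for _, r in inter.iterrows()
        ],
    }
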