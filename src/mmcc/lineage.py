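"""Sub-lineage label collapsing to the five parent immune lineages.

Differential analysis operates on five parent lineages — Monocyte, B,
CD4T, CD8T, NK — obtained by merging fine-grained cluster labels: the NK
group receives NKT and NK bright/dim clusters, the Monocyte group receives
classical/non-classical monocytes and dendritic cells, and so on.  The
mapping ships as an editable table; labels outside it raise an error
rather than being silently dropped, so annotation drift surfaces loudly.
"""

from __future__ import annotations

LINEAGE_SUBLABELS: dict[str, tuple[str, ...]] = {
    "CD4T": (
        "CD4 Naive", "CD4 TCM", "CD4 TEM", "CD4 CTL", "CD4 Proliferating",
        "CD4 T", "Treg",
    ),
    "CD8T": (
        "CD8 Naive", "CD8 TCM", "CD8 TEM", "CD8 Proliferating", "CD8 T",
    ),
    "B": (
        "B naive", "B intermediate", "B memory", "B", "Plasmablast", "Plasma",
    ),
    "NK": (
        "NK", "NK CD56bright", "NK CD56dim", "NK Proliferating", "NKT",
    ),
    "Monocyte": (
        "CD14 Mono", "CD16 Mono", "Monocyte", "cDC", "cDC1", "cDC2", "pDC",
        "DC", "ASDC",
    ),
}

#: sublineage label -> parent lineage
DEFAULT_LINEAGE_MAP: dict[str, str] = {
    sub: parent for parent, subs in LINEAGE_SUBLABELS.items() for sub in subs
}


class UnmappedLineageError(KeyError):
    """A sub-lineage label has no parent-lineage assignment."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(
            f"sub-lineage label {label!r} is not mapped to a parent lineage; "
            "extend the lineage map to include it"
        )


def collapse_lineage(sublineage_label: str, mapping: dict[str, str] | None = None) -> str:
    """Map a sub-lineage cluster label to its parent lineage.

    Parameters
    ----------
    sublineage_label
        Non-empty cluster label, e.g. ``"NK CD56bright"``.
    mapping
        label -> parent table; defaults to :data:`DEFAULT_LINEAGE_MAP`.

    Raises
    ------
    UnmappedLineageError
        If the label is absent from the mapping.
    """
    if not sublineage_label:
        raise ValueError("empty sub-lineage label")
    mapping = DEFAULT_LINEAGE_MAP if mapping is None else mapping
    try:
        return mapping[sublineage_label]
    except KeyError:
        raise UnmappedLineageError(sublineage_label) from None
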