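"""The AAL-90 parcellation node table.

The atlas divides the cerebrum into 90 regions of interest, 45 per
hemisphere, where every left-hemisphere region has a homotopic
(mirror-image) partner on the right.  Downstream stages rely on this
explicit correspondence: hemispheric networks are ordered by homotopic
pair so that row *k* of the left network and row *k* of the right
network refer to the same anatomical region.
"""

from __future__ import annotations

import pandas as pd

# (abbreviation, functional class) for the 45 homotopic region pairs.
AAL90_REGIONS: tuple[tuple[str, str], ...] = (
    ("AMYG", "Paralimbic"),
    ("ANG", "Association"),
    ("ACG", "Paralimbic"),
    ("CAL", "Primary"),
    ("CAU", "Subcortical"),
    ("CUN", "Association"),
    ("FFG", "Association"),
    ("REC", "Paralimbic"),
    ("HES", "Primary"),
    ("HIP", "Subcortical"),
    ("IFGoperc", "Association"),
    ("IFGtriang", "Association"),
    ("IOG", "Association"),
    ("IPL", "Association"),
    ("ITG", "Association"),
    ("INS", "Paralimbic"),
    ("LING", "Association"),
    ("MCG", "Paralimbic"),
    ("MFG", "Association"),
    ("MOG", "Association"),
    ("MTG", "Association"),
    ("OLF", "Paralimbic"),
    ("ORBsup", "Paralimbic"),
    ("ORBinf", "Paralimbic"),
    ("ORBmed", "Paralimbic"),
    ("ORBmid", "Paralimbic"),
    ("PAL", "Subcortical"),
    ("PCL", "Association"),
    ("PHG", "Paralimbic"),
    ("PoCG", "Primary"),
    ("PCG", "Paralimbic"),
    ("PreCG", "Primary"),
    ("PCUN", "Association"),
    ("PUT", "Subcortical"),
    ("ROL", "Association"),
    ("SFGdor", "Association"),
    ("SFGmed", "Association"),
    ("SOG", "Association"),
    ("SPG", "Association"),
    ("STG", "Association"),
    ("SMA", "Association"),
    ("SMG", "Association"),
    ("TPOmid", "Paralimbic"),
    ("TPOsup", "Paralimbic"),
    ("THA", "Subcortical"),
)

N_PAIRS = len(AAL90_REGIONS)
N_REGIONS = 2 * N_PAIRS

NODE_TABLE_COLUMNS = ["region_abbr", "hemisphere", "pair_index", "region_class"]


def default_node_table() -> pd.DataFrame:
    """Return the default 90-row node table in interleaved L/R order.

    Columns: ``region_abbr`` (atlas abbreviation), ``hemisphere``
    (``L``/``R``), ``pair_index`` (1-based homotopic pair identity) and
    ``region_class``.  The whole-brain matrix order alternates left and
    right members of each pair, mirroring the convention of the atlas.
    """
    rows = []
    for k, (abbr, cls) in enumerate(AAL90_REGIONS, start=1):
        rows.append((abbr, "L", k, cls))
        rows.append((abbr, "R", k, cls))
    return pd.DataFrame(rows, columns=NODE_TABLE_COLUMNS)


def node_labels(node_table: pd.DataFrame) -> list[str]:
    """Unique per-node labels, e.g. ``PreCG.L`` — used as TSV headers."""
    return [
        f"{abbr}.{hemi}"
        for abbr, hemi in zip(node_table["region_abbr"], node_table["hemisphere"])
    ]


def validate_node_table(node_table: pd.DataFrame) -> None:
    """Check the homotopic-pairing invariants; raise ``ValueError`` if broken."""
    missing = set(NODE_TABLE_COLUMNS) - set(node_table.columns)
    if missing:
        raise ValueError(f"node table missing columns: {sorted(missing)}")
    if len(node_table) != N_REGIONS:
        raise ValueError(f"node table must have {N_REGIONS} rows, got {len(node_table)}")
    for hemi in ("L", "R"):
        sub = node_table[node_table["hemisphere"] == hemi]
        if len(sub) != N_PAIRS:
            raise ValueError(f"hemisphere {hemi} has {len(sub)} rows, expected {N_PAIRS}")
        if sorted(sub["pair_index"]) != list(range(1, N_PAIRS + 1)):
            raise ValueError(
                f"pair_index values of hemisphere {hemi} are not a bijection onto 1..{N_PAIRS}"
            )
        if sub["region_abbr"].duplicated().any():
            dup = sub.loc[sub["region_abbr"].duplicated(), "region_abbr"].iloc[0]
            raise ValueError(f"duplicate region abbreviation within hemisphere {hemi}: {dup}")
    # both members of a pair must carry the same abbreviation
    by_pair = node_table.pivot(index="pair_index", columns="hemisphere", values="region_abbr")
    mismatched = by_pair[by_pair["L"] != by_pair["R"]]
    if len(mismatched):
        raise ValueError(
            f"homotopic pair {int(mismatched.index[0])} has mismatched abbreviations"
        )


def hemisphere_indices(node_table: pd.DataFrame) -> tuple[list[int], list[int]]:
    """Row positions of left and right nodes, each sorted by pair_index."""
    validate_node_table(node_table)
    out = []
    for hemi in ("L", "R"):
        sub = node_table[node_table["hemisphere"] == hemi]
        out.append(list(sub.sort_values("pair_index").index))
    positions = {idx: pos for pos, idx in enumerate(node_table.index)}
    return tuple([positions[i] for i in idxs] for idxs in out)  # type: ignore[return-value]
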