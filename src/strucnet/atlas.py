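"""Node parcellation table for the 89-region structural connectome.

The connectome nodes are the Desikan–Killiany cortical regions (34 per
hemisphere), nine bilateral subcortical/cerebellar structures, bilateral
cerebellum white matter and the brainstem — 89 nodes in all.  The exact
published cortical subset for this parcellation is not distributed with
the study it emulates, so the standard Desikan–Killiany label set is used
as a faithful stand-in; all analyses depend only on the node count and a
fixed, documented node order.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["N_NODES", "default_atlas", "read_atlas", "write_atlas", "validate_atlas"]

N_NODES = 89

_DK_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
]

_SUBCORTICAL = [
    ("cerebellum-cortex", "cerebellar"),
    ("cerebellum-white-matter", "cerebellar"),
    ("thalamus-proper", "subcortical"),
    ("caudate", "subcortical"),
    ("putamen", "subcortical"),
    ("pallidum", "subcortical"),
    ("hippocampus", "subcortical"),
    ("amygdala", "subcortical"),
    ("accumbens-area", "subcortical"),
    ("ventraldc", "subcortical"),
]


def default_atlas() -> pd.DataFrame:
    """Return the packaged 89-node atlas table.

    Columns: ``node_index`` (contiguous 0..88), ``label`` (unique region
    name), ``hemisphere`` (left/right/midline) and ``class`` (cortical,
    subcortical, cerebellar, brainstem).
    """
    rows = []
    for hemi in ("left", "right"):
        prefix = "lh" if hemi == "left" else "rh"
        for name in _DK_CORTICAL:
            rows.append((f"{prefix}-{name}", hemi, "cortical"))
    for hemi in ("left", "right"):
        prefix = "lh" if hemi == "left" else "rh"
        for name, cls in _SUBCORTICAL:
            rows.append((f"{prefix}-{name}", hemi, cls))
    rows.append(("brainstem", "midline", "brainstem"))
    table = pd.DataFrame(rows, columns=["label", "hemisphere", "class"])
    table.insert(0, "node_index", range(len(table)))
    return table


def validate_atlas(table: pd.DataFrame) -> pd.DataFrame:
    required = {"node_index", "label", "hemisphere", "class"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"atlas table missing columns: {sorted(missing)}")
    if len(table) != N_NODES:
        raise ValueError(f"atlas table must have exactly {N_NODES} rows, got {len(table)}")
    if list(table["node_index"]) != list(range(N_NODES)):
        raise ValueError("node_index must be contiguous from 0")
    if table["label"].duplicated().any():
        dupes = table.loc[table["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate atlas labels: {dupes}")
    bad_hemi = set(table["hemisphere"]) - {"left", "right", "midline"}
    if bad_hemi:
        raise ValueError(f"unknown hemisphere tokens: {sorted(bad_hemi)}")
    bad_cls = set(table["class"]) - {"cortical", "subcortical", "cerebellar", "brainstem"}
    if bad_cls:
        raise ValueError(f"unknown node class tokens: {sorted(bad_cls)}")
    return table


def read_atlas(path) -> pd.DataFrame:
    return validate_atlas(pd.read_csv(path))


def write_atlas(table: pd.DataFrame, path) -> None:
    validate_atlas(table).to_csv(path, index=False)
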