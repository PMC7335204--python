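"""Node atlas for the pain-matrix + default-mode network.

The packaged atlas lists 23 base regions of interest drawn from the
Destrieux, AAL and Brodmann atlases plus an insular subdivision and a
periaqueductal-gray sphere.  Every region except the PAG has a homologous
counterpart in each hemisphere, so lateralization expands the table to a
45-node list.  Node order is fixed (table order, left before right, PAG
last) and every matrix produced by the pipeline inherits it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["NodeAtlas", "load_node_atlas"]

_REQUIRED_COLUMNS = {"short_name", "full_name", "source_atlas", "hemisphere"}
_HEMISPHERE_POLICIES = {"bilateral", "midline"}


@dataclass(frozen=True)
class NodeAtlas:
    """Lateralized node list plus the base-region table it came from."""

    regions: pd.DataFrame = field(repr=False)
    nodes: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def hemisphere_of(self, node: str) -> str:
        if node.startswith("L "):
            return "L"
        if node.startswith("R "):
            return "R"
        return "midline"


def load_node_atlas(path: str | Path | None = None) -> NodeAtlas:
    """Load a base-region table and expand it to the lateralized node list.

    Parameters
    ----------
    path:
        Tab-separated region table with columns ``short_name``, ``full_name``,
        ``source_atlas`` and ``hemisphere`` (``bilateral`` or ``midline``).
        ``None`` loads the packaged pain-matrix + DMN table, whose 22
        bilateral regions and single midline PAG yield 45 nodes.

    Returns
    -------
    NodeAtlas
        ``bilateral`` regions appear as ``"L <name>"`` and ``"R <name>"`` in
        table order (left first); ``midline`` regions keep their bare name.
    """
    if path is None:
        source = importlib.resources.files("restgraph.data") / "node_atlas.tsv"
        with importlib.resources.as_file(source) as p:
            regions = pd.read_csv(p, sep="\t")
    else:
        regions = pd.read_csv(path, sep="\t")

    missing = _REQUIRED_COLUMNS - set(regions.columns)
    if missing:
        raise ValueError(f"atlas table missing required columns: {sorted(missing)}")
    if regions["short_name"].duplicated().any():
        dupes = regions.loc[regions["short_name"].duplicated(), "short_name"].tolist()
        raise ValueError(f"duplicate region names in atlas: {dupes}")
    bad = set(regions["hemisphere"]) - _HEMISPHERE_POLICIES
    if bad:
        raise ValueError(f"unknown hemisphere policy: {sorted(bad)}; expected bilateral|midline")

    lateral: list[str] = []
    midline: list[str] = []
    for _, row in regions.iterrows():
        if row["hemisphere"] == "bilateral":
            lateral.append(f"L {row['short_name']}")
            lateral.append(f"R {row['short_name']}")
        else:
            midline.append(row["short_name"])
    nodes = lateral + midline
    if len(set(nodes)) != len(nodes):
        raise ValueError("lateralized node names are not unique")
    return NodeAtlas(regions=regions, nodes=nodes)
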