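"""Post-processing: TSS state proportions and genome-fraction statistics.

The central readout of the reprogramming model is the proportion of
transcription start sites covered by each state layer over the course of
a simulation, broken down by gene list.  A TSS is a 1-bp point and counts
as covered by a state iff that base lies inside the state's interval set
at the snapshot (an optional symmetric window widens the point).
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import pandas as pd

from .layer_model import RangeSet

logger = logging.getLogger(__name__)

OTHER_LIST_NAME = "all_other_genes"

TssRecord = tuple[str, int, str]  # chrom, 1-based position, gene id


class SummaryError(ValueError):
    pass


def read_tss_bed(path) -> list[TssRecord]:
    """Read 1-bp TSS sites from a BED4 file (name column = gene id)."""
    out: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SummaryError(f"{path}:{lineno}: TSS BED needs 4 columns")
            chrom, start, end, gene = fields[:4]
            start, end = int(start), int(end)
            if end - start != 1:
                raise SummaryError(f"{path}:{lineno}: TSS must be 1-bp intervals")
            out.append((chrom, start + 1, gene))
    if not out:
        raise SummaryError(f"no TSS records in {path}")
    return out


def read_gene_lists(path) -> dict[str, set[str]]:
    """Read a 2-column TSV (gene id, list name) into name -> id-set."""
    lists: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, name = line.split("\t")[:2]
            lists.setdefault(name, set()).add(gene)
    return lists


def tss_state_proportions(
    snapshots: Mapping[int, Mapping[str, RangeSet]],
    tss: Sequence[TssRecord],
    gene_lists: Optional[Mapping[str, set[str]]] = None,
    states: Optional[Sequence[str]] = None,
    window: int = 0,
) -> pd.DataFrame:
    """Per-(cycle, gene list, state) proportion of TSS covered by the state.

    Gene ids named in a list but absent from the TSS set are logged and
    dropped.  TSS belonging to no provided list form the implicit
    ``all_other_genes`` list.
    """
    if not tss:
        raise SummaryError("empty TSS set")
    gene_lists = dict(gene_lists or {})
    known = {g for _, _, g in tss}
    for name, ids in list(gene_lists.items()):
        missing = ids - known
        if missing:
            logger.warning("gene list %s: %d ids missing from TSS set, dropped",
                           name, len(missing))
            gene_lists[name] = ids & known
    listed = set().union(*gene_lists.values()) if gene_lists else set()
    other = known - listed
    if other:
        gene_lists[OTHER_LIST_NAME] = other

    rows = []
    for cycle in sorted(snapshots):
        layers = snapshots[cycle]
        state_names = list(states) if states else list(layers)
        for state in state_names:
            rs = layers[state]
            covered = {
                g for chrom, pos, g in tss
                if rs.overlaps(chrom, pos - window, pos + window)
            }
            for list_name, ids in gene_lists.items():
                n = len(ids)
                rows.append({
                    "cycle": cycle,
                    "gene_list": list_name,
                    "state": state,
                    "proportion": (len(covered & ids) / n) if n else 0.0,
                    "n_tss": n,
                })
    return pd.DataFrame(rows, columns=["cycle", "gene_list", "state",
                                       "proportion", "n_tss"])


def genome_fraction_in_state(layerset_or_layers, layer: str,
                             total_bp: Optional[int] = None) -> float:
    """Fraction of the genome covered by ``layer`` (covered_bp / total bp)."""
    from .layer_model import LayerSet

    if isinstance(layerset_or_layers, LayerSet):
        ls = layerset_or_layers
        return ls.covered_bp(layer) / ls.genome.total_bp
    rs = layerset_or_layers[layer]
    if total_bp is None:
        raise SummaryError("total_bp required when passing a plain layer map")
    return rs.covered_bp / total_bp
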