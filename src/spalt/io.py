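"""Tabular and JSON artifact writers.

TSV dialect: tab-separated, header row, UTF-8, no quoting.  Every pipeline
command writes a JSON run manifest next to its outputs so that any artifact
can be regenerated from config + seed.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .align import Alignment
from .architecture import DomainArchitecture, PresenceMatrix
from .phylo import OrthologyCall
from .scan import ScanResult


def write_hits_tsv(results: Sequence[ScanResult], path) -> None:
    rows = []
    for res in results:
        for feature, cls, start, end, mm in res.all_hits():
            rows.append((res.record.id, feature, cls, start, end, mm))
    df = pd.DataFrame(rows, columns=["record_id", "feature", "class",
                                     "start", "end", "mismatches"])
    df.to_csv(path, sep="\t", index=False)


def architecture_to_dict(arch: DomainArchitecture) -> dict:
    return {
        "record_id": arch.record_id,
        "taxon": arch.taxon,
        "annotations": [
            {"label": a.label, "start": a.start, "end": a.end,
             "degenerate_side": a.degenerate_side}
            for a in arch.annotations
        ],
        "flags": list(arch.flags),
    }


def write_architectures_json(archs: Sequence[DomainArchitecture], path) -> None:
    payload = [architecture_to_dict(a) for a in archs]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_matrix_tsv(matrix: PresenceMatrix, path) -> None:
    matrix.to_tsv(path)


def write_states_tsv(rec, path) -> None:
    """Per-node ancestral states, one row per node, one column per character."""
    names = [rec.node_ids[k] for k in rec.node_ids]
    df = pd.DataFrame(
        {ch: [rec.states[ch][n] for n in names] for ch in rec.characters},
        index=pd.Index(names, name="node"),
    )
    df.to_csv(path, sep="\t")


def write_events_tsv(rec, path) -> None:
    rec.events_frame().to_csv(path, sep="\t", index=False)


def write_calls_tsv(calls: Iterable[OrthologyCall], path) -> None:
    rows = [(c.candidate_id, c.verdict,
             "" if c.support is None else f"{c.support:.3f}",
             ",".join(sorted(c.clade)))
            for c in calls]
    df = pd.DataFrame(rows, columns=["candidate", "verdict", "support", "clade"])
    df.to_csv(path, sep="\t", index=False)


def write_alignment_fasta(msa: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(row), 80):
                fh.write(row[i:i + 80] + "\n")


def write_manifest(path, command: str, inputs: dict, config: dict,
                   seed: int | None = None) -> None:
    manifest = {
        "tool": "spalt",
        "version": __version__,
        "python": platform.python_version(),
        "command": command,
        "inputs": inputs,
        "config": config,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
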