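"""Plain-text serialization: delimited matrices with JSON sidecars.

All numeric payloads are tab-separated text written at full float precision
(``%.17g`` round-trips IEEE doubles exactly); structural metadata lives in a
JSON sidecar next to the matrix file.  A prefix ``foo`` produces
``foo.tsv`` + ``foo.json``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .cells import NonlinearitySpec, SimpleCellBank, ComplexCellSignature
from .groups import FiniteOrthogonalGroup
from .synthetic_data import OrbitDataset

__all__ = [
    "save_matrix", "load_matrix",
    "save_group", "load_group",
    "save_dataset", "load_dataset",
    "save_bank", "load_bank",
    "save_signature_csv",
]

_FMT = "%.17g"


def _ext(prefix: Path, suffix: str) -> Path:
    """Append an extension without clobbering dots inside the prefix name."""
    return prefix.parent / (prefix.name + suffix)


def save_matrix(path, M: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(M, dtype=float)),
               fmt=_FMT, delimiter="\t")


def load_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def _write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def save_group(prefix, group: FiniteOrthogonalGroup) -> None:
    """Group elements as N stacked d×d blocks (row-major) + JSON metadata."""
    prefix = Path(prefix)
    save_matrix(_ext(prefix, ".tsv"),
                group.elements.reshape(group.N * group.d, group.d))
    _write_json(_ext(prefix, ".json"),
                {"kind": group.kind, "d": group.d, "N": group.N,
                 "meta": group.meta})


def load_group(prefix) -> FiniteOrthogonalGroup:
    prefix = Path(prefix)
    meta = json.loads(_ext(prefix, ".json").read_text())
    flat = load_matrix(_ext(prefix, ".tsv"))
    els = flat.reshape(meta["N"], meta["d"], meta["d"])
    return FiniteOrthogonalGroup(els, kind=meta["kind"], meta=meta["meta"])


def save_dataset(prefix, dataset: OrbitDataset) -> None:
    """Stimulus matrix (columns = stimuli) + sidecar + group files."""
    prefix = Path(prefix)
    save_matrix(_ext(prefix, ".tsv"), dataset.stimuli)
    save_matrix(prefix.parent / (prefix.name + ".base.tsv"),
                dataset.base_points)
    save_group(prefix.parent / (prefix.name + ".group"), dataset.group)
    _write_json(_ext(prefix, ".json"), {
        "Q": dataset.Q,
        "N": dataset.group.N,
        "orbit_labels": dataset.orbit_labels.tolist(),
        "element_indices": dataset.element_indices.tolist(),
        "rng_seed": dataset.rng_seed,
        "complete": dataset.complete,
        "group_file": prefix.name + ".group",
    })


def load_dataset(prefix) -> OrbitDataset:
    prefix = Path(prefix)
    meta = json.loads(_ext(prefix, ".json").read_text())
    group = load_group(prefix.parent / meta["group_file"])
    return OrbitDataset(
        group=group,
        base_points=load_matrix(prefix.parent / (prefix.name + ".base.tsv")),
        stimuli=load_matrix(_ext(prefix, ".tsv")),
        orbit_labels=np.asarray(meta["orbit_labels"], dtype=int),
        element_indices=np.asarray(meta["element_indices"], dtype=int),
        rng_seed=meta["rng_seed"],
        complete=meta["complete"],
    )


def save_bank(prefix, bank: SimpleCellBank) -> None:
    prefix = Path(prefix)
    save_matrix(_ext(prefix, ".tsv"), bank.W)
    _write_json(_ext(prefix, ".json"),
                dataclasses.asdict(bank.nonlinearity))


def load_bank(prefix) -> SimpleCellBank:
    prefix = Path(prefix)
    spec = NonlinearitySpec(**json.loads(_ext(prefix, ".json").read_text()))
    return SimpleCellBank(load_matrix(_ext(prefix, ".tsv")), spec)


def save_signature_csv(path, sig: ComplexCellSignature) -> None:
    import pandas as pd

    pd.DataFrame({"threshold": sig.grid.thresholds,
                  "value": sig.values}).to_csv(path, index=False)
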