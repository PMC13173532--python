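"""Plain-text readers and writers.

Everything round-trips through ordinary delimited text or standard structural
formats: descriptor matrices and reports as TSV, fitted CV models as JSON,
coordinates as multi-model PDB (via biotite) or XYZ stacks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .descriptors import DescriptorMatrix, PruningReport
from .hlda import HLDAModel
from .kinetics import FPTRecord

__all__ = [
    "write_descriptor_matrix",
    "read_descriptor_matrix",
    "write_pruning_report",
    "write_model",
    "read_model",
    "write_bias_log",
    "read_bias_log",
    "write_fpt_records",
    "read_fpt_records",
    "read_rmsd_series",
    "write_xyz_stack",
    "read_xyz_stack",
    "write_pdb_stack",
    "read_pdb_stack",
]


def _parse_pair(name: str) -> tuple[int, int]:
    parts = name.split("_")
    if len(parts) != 3 or parts[0] != "d":
        raise ValueError(f"column {name!r} is not a pair label of the form d_p_q")
    return int(parts[1]), int(parts[2])


def write_descriptor_matrix(matrix: DescriptorMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_descriptor_matrix(path: str | Path) -> DescriptorMatrix:
    df = pd.read_csv(path, sep="\t")
    labels = None
    if "state" in df.columns:
        labels = tuple(df.pop("state").astype(str))
    pairs = tuple(_parse_pair(c) for c in df.columns)
    return DescriptorMatrix(values=df.to_numpy(float), pairs=pairs, frame_labels=labels)


def write_pruning_report(report: PruningReport, path: str | Path) -> None:
    report.to_dataframe().to_csv(path, sep="\t", index=False)


def write_model(model: HLDAModel, path: str | Path) -> None:
    payload = {
        "pairs": [list(pq) for pq in model.pairs],
        "weights": model.weights.tolist(),
        "eigenvalue": model.eigenvalue,
        "mean_folded": model.mean_folded.tolist(),
        "mean_unfolded": model.mean_unfolded.tolist(),
        "global_mean": model.global_mean.tolist(),
        "s_w": model.s_w.tolist(),
        "s_b": model.s_b.tolist(),
        "separated": model.separated,
        "sign_convention": model.sign_convention,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path: str | Path) -> HLDAModel:
    payload = json.loads(Path(path).read_text())
    return HLDAModel(
        weights=np.asarray(payload["weights"]),
        eigenvalue=float(payload["eigenvalue"]),
        pairs=tuple(tuple(pq) for pq in payload["pairs"]),
        mean_folded=np.asarray(payload["mean_folded"]),
        mean_unfolded=np.asarray(payload["mean_unfolded"]),
        s_w=np.asarray(payload["s_w"]),
        s_b=np.asarray(payload["s_b"]),
        global_mean=np.asarray(payload["global_mean"]),
        separated=bool(payload["separated"]),
        sign_convention=str(payload["sign_convention"]),
    )


def write_bias_log(
    times: np.ndarray, s: np.ndarray, bias_energy: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame({"time": times, "s": s, "bias_energy": bias_energy}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_bias_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fpt_records(records: Sequence[FPTRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "biased_fpt": [r.biased_fpt for r in records],
            "acceleration": [r.acceleration for r in records],
            "rescaled": [r.rescaled for r in records],
            "crossed": [int(r.crossed) for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_fpt_records(path: str | Path) -> list[FPTRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        FPTRecord(
            biased_fpt=float(r.biased_fpt),
            acceleration=float(r.acceleration),
            rescaled=float(r.rescaled),
            crossed=bool(r.crossed),
        )
        for r in df.itertuples()
    ]


def read_rmsd_series(path: str | Path) -> np.ndarray:
    """Single-column plain text, one RMSD per frame (comments with #)."""
    return np.loadtxt(path, ndmin=1)


def write_xyz_stack(
    frames: np.ndarray, path: str | Path, symbols: Sequence[str] | None = None
) -> None:
    """XYZ trajectory: one block per frame (count, comment, element x y z)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_atoms = frames.shape[1]
    if symbols is None:
        symbols = ["C"] * n_atoms
    with open(path, "w") as fh:
        for i, frame in enumerate(frames):
            fh.write(f"{n_atoms}\nframe {i}\n")
            for sym, (x, y, z) in zip(symbols, frame):
                fh.write(f"{sym} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz_stack(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an XYZ trajectory; returns ``(frames, element symbols)``."""
    lines = Path(path).read_text().splitlines()
    frames = []
    symbols: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError("truncated XYZ block")
        coords = []
        symbols = []
        for ln in block:
            parts = ln.split()
            symbols.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError("no frames found in XYZ file")
    return np.asarray(frames, dtype=float), symbols


def _toy_atom_array(frame: np.ndarray) -> struc.AtomArray:
    n = frame.shape[0]
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(frame, dtype=np.float32)
    arr.atom_name = np.asarray(["CA"] * n)
    arr.res_name = np.asarray(["GLY"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.chain_id = np.asarray(["A"] * n)
    arr.element = np.asarray(["C"] * n)
    return arr


def write_pdb_stack(frames: np.ndarray, path: str | Path) -> None:
    """Write toy coordinates as a multi-model PDB (one Calpha per residue)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    stack = struc.stack([_toy_atom_array(f) for f in frames])
    f = pdbio.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_pdb_stack(
    path: str | Path, atom_names: Sequence[str] | None = ("CA",)
) -> tuple[np.ndarray, np.ndarray]:
    """Read a multi-model PDB; returns ``(frames, residue ids)``.

    ``atom_names`` filters the backbone definition (default Calpha only;
    pass ``("N", "CA", "C", "O")`` for a full-backbone RMSD or ``None`` to
    keep every atom).
    """
    f = pdbio.PDBFile.read(str(path))
    stack = f.get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if atom_names is not None:
        mask = np.isin(stack.atom_name, list(atom_names))
        stack = stack[..., mask]
    return np.asarray(stack.coord, dtype=float), np.asarray(stack.res_id)
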