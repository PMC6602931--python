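"""File formats and persistence: extended-XYZ, the versioned model
container, and run configuration.

The extended-XYZ dialect: line 1 is the atom count; line 2 carries
whitespace-separated ``key=value`` pairs including a ``Properties=`` string
(``species:S:1:pos:R:3`` plus ``:forces:R:3`` when forces are present) and
optional ``energy_low=``, ``energy_high=``, ``molecule_id=`` entries.
Coordinates are Å, energies kcal/mol, forces kcal/mol/Å; numerics are
written with 17 significant digits so round-trips are exact to double
precision.

Models persist as an .npz container with a JSON header (format version,
AEVSpec, widths, activation, seeds, self-energies) and a SHA-256 checksum
over the parameter payload.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import yaml

from .conformation import Conformation
from .featurization import AEVSpec
from .model import Ensemble, NNPModel

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# extended-XYZ
# ---------------------------------------------------------------------------
def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_extxyz(conformations: Sequence[Conformation], path) -> None:
    lines: List[str] = []
    for c in conformations:
        props = "species:S:1:pos:R:3" + (":forces:R:3" if c.forces is not None else "")
        head = [f"Properties={props}", f"molecule_id={c.molecule_id}"]
        if c.energy_low is not None:
            head.append(f"energy_low={_fmt(c.energy_low)}")
        if c.energy_high is not None:
            head.append(f"energy_high={_fmt(c.energy_high)}")
        lines.append(str(c.n_atoms))
        lines.append(" ".join(head))
        for i, s in enumerate(c.species):
            row = [s] + [_fmt(v) for v in c.coordinates[i]]
            if c.forces is not None:
                row += [_fmt(v) for v in c.forces[i]]
            lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_comment(comment: str) -> Dict[str, str]:
    out = {}
    for tok in comment.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v.strip('"')
    return out


def read_extxyz(path) -> List[Conformation]:
    """Parse an extended-XYZ file; malformed frames raise with the line
    number of the offence."""
    text = Path(path).read_text().splitlines()
    out: List[Conformation] = []
    ln = 0
    frame = 0
    while ln < len(text):
        if not text[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(text[ln].strip())
        except ValueError as exc:
            raise ValueError(f"line {ln + 1}: expected an atom count") from exc
        if ln + 2 + natoms > len(text):
            raise ValueError(
                f"line {ln + 1}: frame declares {natoms} atoms but the file "
                f"ends at line {len(text)}"
            )
        meta = _parse_comment(text[ln + 1])
        has_forces = "forces" in meta.get("Properties", "")
        species = []
        coords = np.zeros((natoms, 3))
        forces = np.zeros((natoms, 3)) if has_forces else None
        for a in range(natoms):
            lineno = ln + 2 + a
            parts = text[lineno].split()
            want = 7 if has_forces else 4
            if len(parts) < want:
                raise ValueError(
                    f"line {lineno + 1}: expected {want} columns, got {len(parts)}"
                )
            species.append(parts[0])
            coords[a] = [float(v) for v in parts[1:4]]
            if has_forces:
                forces[a] = [float(v) for v in parts[4:7]]
        out.append(
            Conformation(
                molecule_id=meta.get("molecule_id", f"frame{frame}"),
                species=tuple(species),
                coordinates=coords,
                energy_low=float(meta["energy_low"]) if "energy_low" in meta else None,
                energy_high=float(meta["energy_high"]) if "energy_high" in meta else None,
                forces=forces,
            )
        )
        frame += 1
        ln += 2 + natoms
    return out


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------
def _model_arrays(model: NNPModel, prefix: str) -> Dict[str, np.ndarray]:
    arrays = {}
    for e, layers in model.element_networks.items():
        for li, (W, b) in enumerate(layers):
            arrays[f"{prefix}{e}_W{li}"] = W
            arrays[f"{prefix}{e}_b{li}"] = b
    if model.input_shift is not None:
        arrays[f"{prefix}input_shift"] = model.input_shift
        arrays[f"{prefix}input_scale"] = model.input_scale
    return arrays


def _model_header(model: NNPModel) -> dict:
    return {
        "spec": model.spec.to_dict(),
        "widths": list(model.widths),
        "activation": model.activation,
        "seed": model.seed,
        "self_energies": model.self_energies,
        "standardized": model.input_shift is not None,
    }


def _checksum(arrays: Dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for k in sorted(arrays):
        h.update(k.encode())
        h.update(np.ascontiguousarray(arrays[k]).tobytes())
    return h.hexdigest()


def save_model(model_or_ensemble: Union[NNPModel, Ensemble], path) -> None:
    """Write the versioned container; `load_model` reproduces predictions
    bit-for-bit."""
    if isinstance(model_or_ensemble, Ensemble):
        members = model_or_ensemble.members
        header = {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": "ensemble",
            "member_seeds": list(model_or_ensemble.member_seeds),
            "members": [_model_header(m) for m in members],
        }
        arrays = {}
        for mi, m in enumerate(members):
            arrays.update(_model_arrays(m, f"m{mi}_"))
    else:
        m = model_or_ensemble
        header = {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": "model",
            "members": [_model_header(m)],
        }
        arrays = _model_arrays(m, "m0_")
    header["checksum"] = _checksum(arrays)
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def _rebuild_member(header: dict, arrays, prefix: str) -> NNPModel:
    spec = AEVSpec.from_dict(header["spec"])
    widths = tuple(header["widths"])
    nets = {}
    for e in spec.supported_elements:
        layers = []
        for li in range(len(widths) + 1):
            layers.append(
                (arrays[f"{prefix}{e}_W{li}"].copy(), arrays[f"{prefix}{e}_b{li}"].copy())
            )
        nets[e] = layers
    return NNPModel(
        spec=spec,
        widths=widths,
        element_networks=nets,
        self_energies={k: float(v) for k, v in header["self_energies"].items()},
        seed=int(header.get("seed", 0)),
        activation=header.get("activation", "celu"),
        input_shift=arrays[f"{prefix}input_shift"].copy() if header.get("standardized") else None,
        input_scale=arrays[f"{prefix}input_scale"].copy() if header.get("standardized") else None,
    )


def load_model(path) -> Union[NNPModel, Ensemble]:
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    header = json.loads(bytes(arrays.pop("__header__")).decode())
    version = header.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model container version {version!r} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    if header["checksum"] != _checksum(arrays):
        raise ValueError("model container checksum mismatch: file corrupted")
    if header["kind"] == "model":
        return _rebuild_member(header["members"][0], arrays, "m0_")
    members = [
        _rebuild_member(h, arrays, f"m{mi}_") for mi, h in enumerate(header["members"])
    ]
    return Ensemble(members=members, member_seeds=list(header["member_seeds"]))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------
_RUNCONFIG_KEYS = {
    "aev", "train", "transfer", "active_learning", "freeze",
    "evaluation_window", "master_seed", "log_level", "output_dir",
    "corpus",
}


def load_run_config(path) -> dict:
    """YAML run configuration; unknown top-level keys are rejected by
    name."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(cfg) - _RUNCONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return cfg


def write_manifest(path, **entries) -> None:
    """Reproducibility manifest (config, seeds, versions) for a run."""
    import nnpkit

    payload = {"nnpkit_version": getattr(nnpkit, "__version__", "0"), **entries}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
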