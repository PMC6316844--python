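"""Readers and writers for the plain-text formats shared by all stages.

Formats: batch-sample CSV, isotherm CSV (with a ``# key=value`` metadata
preamble carrying the nucleotide/mineral specs, so an isotherm file is
self-contained), normalized-isotherm CSV, gas-isotherm CSV, DIS decomposition
CSV, and an extended-XYZ trajectory dialect (comment line carrying time and
box) with a roles sidecar CSV.  All floats are serialized with 17 significant
digits so every artifact round-trips bit-identically; readers reject
malformed files with diagnostics naming the file and, where line-oriented,
the line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dis import DISDecomposition, GasIsotherm
from .isotherm import (
    BatchSample,
    Conditions,
    Isotherm,
    IsothermPoint,
    MineralSpec,
    NucleotideSpec,
    concentration_from_absorbance,
)
from .md import TrajectoryFrame
from .normalization import NormalizedIsotherm, NormPoint

__all__ = [
    "fmt_float",
    "write_batch_csv",
    "read_batch_csv",
    "samples_from_batch",
    "write_isotherm_csv",
    "read_isotherm_csv",
    "write_normalized_csv",
    "read_normalized_csv",
    "write_gas_csv",
    "read_gas_csv",
    "write_dis_csv",
    "write_trajectory",
    "read_trajectory",
    "file_sha256",
    "write_provenance",
]


def fmt_float(x: float) -> str:
    """17-significant-digit decimal form; guarantees float round-trip."""
    return format(float(x), ".17g")


def _salts_str(composition) -> str:
    items = sorted(dict(composition).items())
    return ";".join(f"{k}={fmt_float(v)}" for k, v in items)


def _parse_salts(s: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if not s or s != s:  # empty or NaN
        return out
    for part in str(s).split(";"):
        if not part:
            continue
        try:
            k, v = part.split("=")
            out[k] = float(v)
        except ValueError as exc:
            raise ValueError(f"malformed salts field {part!r}") from exc
    return out


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# batch samples

BATCH_COLUMNS = [
    "sample_id", "nucleotide", "mineral", "c0_mol_per_L", "ceq_mol_per_L",
    "volume_L", "mass_g", "ph", "temperature_C", "salts", "replicate_id",
]


def write_batch_csv(
    path,
    samples: Iterable[BatchSample],
    nucleotide: str,
    mineral: str,
) -> None:
    rows = []
    for i, s in enumerate(samples):
        rows.append({
            "sample_id": f"s{i:04d}",
            "nucleotide": nucleotide,
            "mineral": mineral,
            "c0_mol_per_L": fmt_float(s.initial_concentration),
            "ceq_mol_per_L": fmt_float(s.equilibrium_concentration),
            "volume_L": fmt_float(s.solution_volume),
            "mass_g": fmt_float(s.mineral_mass),
            "ph": fmt_float(s.ph),
            "temperature_C": fmt_float(s.temperature),
            "salts": _salts_str(s.solution_composition),
            "replicate_id": s.replicate_id,
        })
    pd.DataFrame(rows, columns=BATCH_COLUMNS).to_csv(path, index=False)


def read_batch_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"salts": str}, keep_default_na=False, float_precision="round_trip")
    has_conc = {"c0_mol_per_L", "ceq_mol_per_L"} <= set(df.columns)
    has_abs = {"absorbance_initial", "absorbance_equilibrium"} <= set(df.columns)
    if not (has_conc or has_abs):
        raise ValueError(
            f"{path}: need either c0_mol_per_L/ceq_mol_per_L or "
            "absorbance_initial/absorbance_equilibrium columns"
        )
    _require_columns(df, ["nucleotide", "mineral", "volume_L", "mass_g"], path)
    return df


def samples_from_batch(
    df: pd.DataFrame,
    spec: NucleotideSpec | None = None,
    path_length: float = 1.0,
) -> list[BatchSample]:
    """Convert a validated batch table to samples.

    Absorbance columns, when present instead of concentrations, are converted
    through Beer-Lambert using `spec` and `path_length`.
    """
    samples = []
    for idx, row in df.iterrows():
        if "c0_mol_per_L" in df.columns:
            c0, ceq = float(row["c0_mol_per_L"]), float(row["ceq_mol_per_L"])
        else:
            if spec is None:
                raise ValueError("absorbance input requires a NucleotideSpec")
            c0 = concentration_from_absorbance(float(row["absorbance_initial"]), spec, path_length)
            ceq = concentration_from_absorbance(
                float(row["absorbance_equilibrium"]), spec, path_length
            )
        samples.append(
            BatchSample(
                initial_concentration=c0,
                equilibrium_concentration=ceq,
                solution_volume=float(row["volume_L"]),
                mineral_mass=float(row["mass_g"]),
                ph=float(row.get("ph", 7.0)),
                temperature=float(row.get("temperature_C", 25.0)),
                solution_composition=_parse_salts(row.get("salts", "")),
                replicate_id=int(row.get("replicate_id", 0)),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# isotherms (self-contained: specs travel in the preamble)

def _preamble(iso: Isotherm) -> list[str]:
    n, m, c = iso.nucleotide, iso.mineral, iso.conditions
    pairs = [
        ("nucleotide", n.name),
        ("molecular_weight", fmt_float(n.molecular_weight)),
        ("solubility_mol_per_L", fmt_float(n.solubility)),
        ("pka_values", ";".join(fmt_float(p) for p in n.pka_values)),
        ("extinction_coefficient", fmt_float(n.extinction_coefficient)),
        ("wavelength_nm", fmt_float(n.wavelength)),
        ("mineral", m.name),
        ("swelling", str(m.swelling).lower()),
        ("ssa_total_m2_per_g", fmt_float(m.ssa_total)),
        ("ssa_basal_m2_per_g", fmt_float(m.ssa_basal)),
        ("ssa_edge_m2_per_g", fmt_float(m.ssa_edge)),
        ("point_of_zero_charge",
         "" if m.point_of_zero_charge is None else fmt_float(m.point_of_zero_charge)),
        ("ph", fmt_float(c.ph)),
        ("temperature_C", fmt_float(c.temperature)),
        ("salts", ";".join(f"{k}={fmt_float(v)}" for k, v in c.composition)),
    ]
    return [f"# {k}={v}" for k, v in pairs]


def write_isotherm_csv(path, iso: Isotherm) -> None:
    lines = _preamble(iso)
    lines.append("nucleotide,mineral,ceq_mol_per_L,q_mol_per_g,sd_q_mol_per_g")
    for p in iso.points:
        lines.append(
            f"{iso.nucleotide.name},{iso.mineral.name},"
            f"{fmt_float(p.c_eq)},{fmt_float(p.q_ads)},{fmt_float(p.sd_q)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_isotherm_csv(path) -> Isotherm:
    meta: dict[str, str] = {}
    rows: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    k, v = line.lstrip("# ").split("=", 1)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed metadata line {line!r}")
                meta[k] = v
            else:
                rows.append(line)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    header = rows[0].split(",")
    expected = ["nucleotide", "mineral", "ceq_mol_per_L", "q_mol_per_g", "sd_q_mol_per_g"]
    if header != expected:
        raise ValueError(f"{path}: unexpected header {header}; expected {expected}")
    points = []
    for lineno, row in enumerate(rows[1:], 2):
        parts = row.split(",")
        if len(parts) != 5:
            raise ValueError(f"{path}: data row {lineno} has {len(parts)} fields, expected 5")
        points.append(IsothermPoint(float(parts[2]), float(parts[3]), float(parts[4])))
    try:
        nucleotide = NucleotideSpec(
            name=meta["nucleotide"],
            molecular_weight=float(meta["molecular_weight"]),
            solubility=float(meta["solubility_mol_per_L"]),
            pka_values=tuple(float(p) for p in meta["pka_values"].split(";") if p),
            extinction_coefficient=float(meta["extinction_coefficient"]),
            wavelength=float(meta["wavelength_nm"]),
        )
        mineral = MineralSpec(
            name=meta["mineral"],
            swelling=meta["swelling"] == "true",
            ssa_total=float(meta["ssa_total_m2_per_g"]),
            ssa_basal=float(meta["ssa_basal_m2_per_g"]),
            ssa_edge=float(meta["ssa_edge_m2_per_g"]),
            point_of_zero_charge=(
                float(meta["point_of_zero_charge"]) if meta.get("point_of_zero_charge") else None
            ),
        )
        conditions = Conditions.from_mapping(
            float(meta["ph"]), float(meta["temperature_C"]), _parse_salts(meta.get("salts", ""))
        )
    except KeyError as exc:
        raise ValueError(f"{path}: metadata preamble missing key {exc}") from None
    return Isotherm(tuple(points), nucleotide, mineral, conditions)


# ---------------------------------------------------------------------------
# normalized isotherms

def write_normalized_csv(path, norm: NormalizedIsotherm) -> None:
    xcol = "x_reduced" if norm.concentration_mode == "reduced" else "ceq_mol_per_L"
    lines = [f"{xcol},density_mol_per_m2,sd,basis,nucleotide,mineral"]
    for p in norm.points:
        lines.append(
            f"{fmt_float(p.x)},{fmt_float(p.d)},{fmt_float(p.sd_d)},"
            f"{norm.basis},{norm.nucleotide},{norm.mineral}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_normalized_csv(path) -> NormalizedIsotherm:
    df = pd.read_csv(path, float_precision="round_trip")
    if "x_reduced" in df.columns:
        mode, xcol = "reduced", "x_reduced"
    elif "ceq_mol_per_L" in df.columns:
        mode, xcol = "raw", "ceq_mol_per_L"
    else:
        raise ValueError(f"{path}: need an x_reduced or ceq_mol_per_L column")
    _require_columns(df, ["density_mol_per_m2", "sd", "basis", "nucleotide", "mineral"], path)
    pts = tuple(
        NormPoint(float(r[xcol]), float(r["density_mol_per_m2"]), float(r["sd"]))
        for _, r in df.iterrows()
    )
    return NormalizedIsotherm(
        pts, str(df["basis"].iloc[0]), mode,
        str(df["nucleotide"].iloc[0]), str(df["mineral"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# gas isotherms and DIS reports

def write_gas_csv(path, gas: GasIsotherm) -> None:
    lines = ["p_over_p0,v_ads_cm3stp_per_g"]
    for p, v in zip(gas.p_over_p0, gas.v_ads):
        lines.append(f"{fmt_float(p)},{fmt_float(v)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gas_csv(path) -> GasIsotherm:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["p_over_p0", "v_ads_cm3stp_per_g"], path)
    return GasIsotherm(
        tuple(float(x) for x in df["p_over_p0"]),
        tuple(float(x) for x in df["v_ads_cm3stp_per_g"]),
    )


def write_dis_csv(path, dec: DISDecomposition) -> None:
    lines = ["domain_id,v_m,u_half,omega,label,area_m2_per_g,edge_fraction,residual_rms"]
    for i, d in enumerate(dec.domains):
        area = "" if dec.areas is None else fmt_float(dec.areas[i])
        lines.append(
            f"{i},{fmt_float(d.v_m)},{fmt_float(d.u_half)},{fmt_float(d.omega)},"
            f"{d.label},{area},{fmt_float(dec.edge_fraction)},{fmt_float(dec.residual_rms)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# trajectories: extended-XYZ dialect + roles sidecar

def write_trajectory(xyz_path, roles_path, frames: Sequence[TrajectoryFrame]) -> None:
    """Write frames as extended XYZ (atom count, ``time_ns=... box=lx,ly,lz``
    comment, element + coordinates) and a per-atom roles sidecar CSV
    (atom_index, element, role, charge, ring_flag) shared by all frames."""
    if not frames:
        raise ValueError("no frames to write")
    first = frames[0]
    with open(xyz_path, "w", encoding="utf-8") as fh:
        for f in frames:
            n = f.coordinates.shape[0]
            box = ",".join(fmt_float(b) for b in f.box)
            fh.write(f"{n}\ntime_ns={fmt_float(f.time)} box={box}\n")
            elements = f.elements or ("X",) * n
            for el, (x, y, z) in zip(elements, f.coordinates):
                fh.write(f"{el} {fmt_float(x)} {fmt_float(y)} {fmt_float(z)}\n")
    ring = set(first.ring_atoms)
    rows = [
        {
            "atom_index": i,
            "element": (first.elements or ("X",) * len(first.roles))[i],
            "role": first.roles[i],
            "charge": fmt_float(first.charges[i]),
            "ring_flag": int(i in ring),
        }
        for i in range(len(first.roles))
    ]
    pd.DataFrame(rows).to_csv(roles_path, index=False)


def read_trajectory(xyz_path, roles_path) -> list[TrajectoryFrame]:
    roles_df = pd.read_csv(roles_path, float_precision="round_trip")
    _require_columns(roles_df, ["atom_index", "role", "charge", "ring_flag"], roles_path)
    roles_df = roles_df.sort_values("atom_index")
    roles = tuple(roles_df["role"])
    charges = roles_df["charge"].to_numpy(dtype=float)
    ring = tuple(int(i) for i in roles_df.loc[roles_df["ring_flag"] == 1, "atom_index"])
    elements = (
        tuple(roles_df["element"]) if "element" in roles_df.columns else ("X",) * len(roles)
    )

    frames: list[TrajectoryFrame] = []
    with open(xyz_path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i, lineno = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
        except ValueError:
            raise ValueError(f"{xyz_path}:{i + 1}: expected an atom count, got {lines[i]!r}")
        if i + 1 >= len(lines):
            raise ValueError(f"{xyz_path}:{i + 1}: truncated frame header")
        comment = lines[i + 1]
        fields = dict(part.split("=", 1) for part in comment.split() if "=" in part)
        if "box" not in fields or "time_ns" not in fields:
            raise ValueError(f"{xyz_path}:{i + 2}: comment must carry time_ns= and box=")
        box = tuple(float(b) for b in fields["box"].split(","))
        if len(box) != 3:
            raise ValueError(
                f"{xyz_path}:{i + 2}: only orthorhombic boxes (3 edge lengths) are supported"
            )
        if i + 2 + n > len(lines):
            raise ValueError(f"{xyz_path}:{i + 1}: frame declares {n} atoms but file ends early")
        coords = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) != 4:
                raise ValueError(f"{xyz_path}:{i + 3 + j}: expected 'El x y z'")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if n != len(roles):
            raise ValueError(
                f"{xyz_path}:{i + 1}: {n} atoms but roles sidecar lists {len(roles)}"
            )
        frames.append(
            TrajectoryFrame(
                time=float(fields["time_ns"]), box=box, coordinates=coords,
                roles=roles, charges=charges.copy(), ring_atoms=ring, elements=elements,
            )
        )
        i += 2 + n
    if not frames:
        raise ValueError(f"{xyz_path}: no frames found")
    return frames


# ---------------------------------------------------------------------------
# provenance

def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(path, *, inputs: Sequence[str], seed: int | None, config: dict) -> None:
    """Deterministic provenance record: input hashes, seed, resolved config,
    and tool version (no timestamps, so reruns are byte-identical)."""
    from . import __version__

    record = {
        "tool": "claysorb",
        "version": __version__,
        "seed": seed,
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "config": config,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n", encoding="utf-8")
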