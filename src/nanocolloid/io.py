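"""File formats: centroid sets (CSV/XYZ), SAXS curves (3-column ASCII),
tabular RDF/PMF/census output, and JSON reports.

Centroid files carry their box metadata in '#' comment headers so a frame is
self-describing; coordinates are written with 17 significant digits so a
write/read round trip is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .aggregation import ClusterCensus
from .potentials import TwoYukawaPotential, YukawaTerm, Environment
from .saxs import SAXSCurve, SAXSFitResult, SolutionState
from .simulate import Box, ParticleConfiguration
from .structure import PMFCurve, PMFFeatures, RDFCurve

__all__ = [
    "read_centroids",
    "write_centroids",
    "read_saxs_dat",
    "write_saxs_dat",
    "write_rdf_csv",
    "read_rdf_csv",
    "write_pmf_csv",
    "read_pmf_csv",
    "write_census_csv",
    "write_features_json",
    "write_fit_json",
    "read_fit_json",
]

_FMT = "%.17g"


def _boundary_words(box: Box) -> str:
    return " ".join("periodic" if p else "wall" for p in box.periodic)


def _parse_box(meta: dict) -> Box:
    if "box_nm" not in meta:
        raise ValueError("missing box metadata field 'box_nm'")
    lengths = tuple(float(v) for v in meta["box_nm"].split())
    boundary = meta.get("boundary", "periodic periodic periodic").split()
    periodic = tuple(w == "periodic" for w in boundary)
    return Box(lengths=lengths, periodic=periodic)


def write_centroids(config: ParticleConfiguration, path: str | Path,
                    fmt: str | None = None) -> None:
    """Write a centroid set as CSV (default) or XYZ, inferred from the suffix."""
    path = Path(path)
    fmt = fmt or ("xyz" if path.suffix.lower() == ".xyz" else "csv")
    lines: list[str] = []
    if fmt == "csv":
        lines.append("# box_nm: " + " ".join(_FMT % L for L in config.box.lengths))
        lines.append("# boundary: " + _boundary_words(config.box))
        lines.append("# provenance: " + config.provenance)
        lines.append("x_nm,y_nm,z_nm")
        for p in config.positions:
            lines.append(",".join(_FMT % v for v in p))
    elif fmt == "xyz":
        meta = {
            "box_nm": " ".join(_FMT % L for L in config.box.lengths),
            "boundary": _boundary_words(config.box),
            "provenance": config.provenance,
        }
        lines.append(str(config.n_particles))
        lines.append(json.dumps(meta))
        for p in config.positions:
            lines.append("P " + " ".join(_FMT % v for v in p))
    else:
        raise ValueError(f"unknown centroid format {fmt!r}")
    path.write_text("\n".join(lines) + "\n")


def read_centroids(path: str | Path, fmt: str | None = None) -> ParticleConfiguration:
    """Read a centroid set (CSV or XYZ); box metadata must be present."""
    path = Path(path)
    fmt = fmt or ("xyz" if path.suffix.lower() == ".xyz" else "csv")
    text = path.read_text().splitlines()
    if fmt == "xyz":
        meta = json.loads(text[1])
        box = _parse_box(meta)
        rows = []
        for ln, line in enumerate(text[2:], start=3):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 'label x y z', got {line!r}")
            rows.append(_parse_coords(parts[1:], path, ln))
        prov = meta.get("provenance", "imported")
        return ParticleConfiguration(positions=np.array(rows).reshape(-1, 3),
                                     box=box, provenance=prov)
    if fmt != "csv":
        raise ValueError(f"unknown centroid format {fmt!r}")
    meta: dict[str, str] = {}
    rows = []
    header_seen = False
    for ln, line in enumerate(text, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if ":" in s:
                key, _, val = s.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            header_seen = True  # column header line
            continue
        parts = s.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 comma-separated values, got {s!r}")
        rows.append(_parse_coords(parts, path, ln))
    box = _parse_box(meta)
    return ParticleConfiguration(positions=np.array(rows).reshape(-1, 3), box=box,
                                 provenance=meta.get("provenance", "imported"))


def _parse_coords(parts: list[str], path: Path, ln: int) -> list[float]:
    try:
        vals = [float(v) for v in parts]
    except ValueError as err:
        raise ValueError(f"{path}:{ln}: malformed coordinate: {err}") from err
    if not all(np.isfinite(vals)):
        raise ValueError(f"{path}:{ln}: non-finite coordinate in row {parts}")
    return vals


# ---------------------------------------------------------------------------
# SAXS curves
# ---------------------------------------------------------------------------

def write_saxs_dat(curve: SAXSCurve, path: str | Path) -> None:
    """3-column ASCII (q_nm^-1, I, sigma_I), '#' comment header."""
    path = Path(path)
    lines = ["# q_unit: nm^-1", "# columns: q I" + (" sigma_I" if curve.sigma_I is not None else "")]
    for i in range(len(curve.q)):
        row = [_FMT % curve.q[i], _FMT % curve.I[i]]
        if curve.sigma_I is not None:
            row.append(_FMT % curve.sigma_I[i])
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_saxs_dat(path: str | Path, q_unit: str | None = None) -> SAXSCurve:
    """Read a 2- or 3-column ASCII curve; Angstrom^-1 input is converted to nm^-1.

    The unit comes from a ``# q_unit:`` header or the ``q_unit`` argument
    ("nm^-1" default, "A^-1" accepted).
    """
    path = Path(path)
    header_unit = None
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if "q_unit:" in s:
                header_unit = s.split("q_unit:")[1].strip()
            continue
        parts = s.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{ln}: expected 2 or 3 columns, got {s!r}")
        try:
            rows.append([float(v) for v in parts])
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: malformed value: {err}") from err
    unit = q_unit or header_unit or "nm^-1"
    factor = {"nm^-1": 1.0, "A^-1": 10.0, "angstrom^-1": 10.0}.get(unit)
    if factor is None:
        raise ValueError(f"unknown q unit {unit!r}")
    arr = np.array(rows)
    sigma = arr[:, 2] if arr.shape[1] == 3 else None
    return SAXSCurve(q=arr[:, 0] * factor, I=arr[:, 1], sigma_I=sigma)


# ---------------------------------------------------------------------------
# tables and reports
# ---------------------------------------------------------------------------

def write_rdf_csv(rdf: RDFCurve, path: str | Path) -> None:
    lines = [
        "# n_particles: %d" % rdf.n_particles,
        "# number_concentration_m3: " + _FMT % rdf.number_concentration,
        "# bin_width_nm: " + _FMT % (rdf.bin_edges[1] - rdf.bin_edges[0]),
        "r_nm,g,pair_count",
    ]
    for r, g, c in zip(rdf.bin_centers, rdf.g, rdf.pair_counts):
        lines.append(f"{_FMT % r},{_FMT % g},{int(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rdf_csv(path: str | Path) -> RDFCurve:
    meta: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            key, _, val = s.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
            continue
        if s.startswith("r_nm"):
            continue
        r, g, c = s.split(",")
        rows.append((float(r), float(g), int(c)))
    arr = np.array([(r, g) for r, g, _ in rows])
    counts = np.array([c for _, _, c in rows])
    width = float(meta["bin_width_nm"])
    centers = arr[:, 0]
    edges = np.concatenate([centers - width / 2.0, [centers[-1] + width / 2.0]])
    edges = np.where(np.abs(edges) < 1e-12, 0.0, edges)
    return RDFCurve(bin_edges=edges, g=arr[:, 1], pair_counts=counts,
                    n_particles=int(meta["n_particles"]),
                    number_concentration=float(meta["number_concentration_m3"]))


def write_pmf_csv(pmf: PMFCurve, path: str | Path) -> None:
    lines = ["# temperature_K: " + _FMT % pmf.temperature_K, "r_nm,W_kT"]
    for r, w in zip(pmf.bin_centers, pmf.W):
        lines.append(f"{_FMT % r},{'inf' if np.isinf(w) else _FMT % w}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pmf_csv(path: str | Path) -> PMFCurve:
    temp = 293.15
    rows = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("r_nm"):
            continue
        if s.startswith("#"):
            if "temperature_K:" in s:
                temp = float(s.split(":")[1])
            continue
        r, w = s.split(",")
        rows.append((float(r), float(w)))
    arr = np.array(rows)
    return PMFCurve(bin_centers=arr[:, 0], W=arr[:, 1], temperature_K=temp)


def write_census_csv(c: ClusterCensus, path: str | Path) -> None:
    lines = ["size_class,percentage,mole_fraction,aggregate_count"]
    for k in range(len(c.size_classes)):
        label = str(c.size_classes[k])
        if c.pooled_top and k == len(c.size_classes) - 1:
            label = f">={label}"
        lines.append(f"{label},{_FMT % c.percentage[k]},{_FMT % c.mole_fraction[k]},"
                     f"{int(c.counts[k])}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_features_json(features: PMFFeatures, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(features), indent=2, sort_keys=True) + "\n")


def write_fit_json(result: SAXSFitResult, path: str | Path) -> None:
    d = {
        "params": result.params_dict(),
        "uncertainties": result.uncertainties,
        "redchi": result.redchi,
        "success": result.success,
        "closure": result.closure,
        "nfev": result.nfev,
        "message": result.message,
        "number_concentration_m3": result.solution.number_concentration,
    }
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_fit_json(path: str | Path) -> SAXSFitResult:
    d = json.loads(Path(path).read_text())
    p = d["params"]
    pot = TwoYukawaPotential(sigma=p["sigma"],
                             term_1=YukawaTerm(p["K1"], p["Z1"]),
                             term_2=YukawaTerm(p["K2"], p["Z2"]),
                             environment=Environment())
    return SAXSFitResult(
        potential=pot,
        solution=SolutionState.from_volume_fraction(p["phi"], p["sigma"]),
        scale=p["scale"], background=p["background"],
        uncertainties=d.get("uncertainties", {}),
        redchi=d["redchi"], success=d["success"], closure=d["closure"],
        nfev=d.get("nfev", 0), message=d.get("message", ""))
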