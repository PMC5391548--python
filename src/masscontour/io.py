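"""Readers and writers for boundary files, signatures and feature tables.

Two contour input formats are supported:

* overlay boundary text files in the DDSM dialect — lesion blocks with a
  ``BOUNDARY`` section whose data line is ``start_column start_row code
  code ... #`` (Freeman chain code);
* plain CSV vertex lists with an ``x,y`` header.

Signatures export as CSV with columns ``index,h,h_p,h_q,theta``; feature
tables as one row per (contour, feature, C) with ``v1..vC`` columns; cohort
manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ChainCodeError
from .geometry import Contour, Signature, contour_to_chain, parse_chain_code

__all__ = [
    "read_overlay",
    "write_overlay",
    "read_vertices_csv",
    "write_vertices_csv",
    "read_contour",
    "write_signature_csv",
    "write_feature_table_csv",
    "read_manifest",
    "write_manifest",
]


def read_overlay(path, direction_map=None, on_open: str = "error") -> dict[str, Contour]:
    """Parse every lesion boundary block in an overlay file.

    Returns a mapping lesion-name -> contour.  Lesions are named by their
    ``ABNORMALITY`` header when present, otherwise ``lesion_<k>``.
    """
    path = Path(path)
    text = path.read_text()
    contours: dict[str, Contour] = {}
    name = None
    k = 0
    lines = iter(text.splitlines())
    for line in lines:
        stripped = line.strip()
        if stripped.upper().startswith("ABNORMALITY"):
            name = stripped.replace(" ", "_").lower()
        if stripped.upper().startswith("BOUNDARY"):
            tokens: list[str] = stripped.split()[1:]  # data may share the line
            while "#" not in tokens:
                try:
                    tokens.extend(next(lines).split())
                except StopIteration:
                    raise ChainCodeError(
                        f"{path.name}: BOUNDARY section not terminated by '#'"
                    )
            tokens = tokens[: tokens.index("#")]
            if len(tokens) < 3:
                raise ChainCodeError(f"{path.name}: BOUNDARY needs start pixel + codes")
            start = (int(tokens[0]), int(tokens[1]))
            codes = [int(t) for t in tokens[2:]]
            k += 1
            lesion = name or f"lesion_{k}"
            contour = parse_chain_code(
                start, codes, direction_map=direction_map, on_open=on_open
            )
            contours[lesion] = Contour(contour.points, contour_id=f"{path.stem}:{lesion}")
            name = None
    if not contours:
        raise ChainCodeError(f"{path.name}: no BOUNDARY section found")
    return contours


def write_overlay(path, contours: dict[str, Contour] | list[Contour], metadata=None) -> None:
    """Write contours as overlay-dialect boundary blocks (chain-code encoded)."""
    if isinstance(contours, dict):
        items = list(contours.items())
    else:
        items = [(c.contour_id or f"lesion_{i + 1}", c) for i, c in enumerate(contours)]
    meta = metadata or {}
    out = [f"TOTAL_ABNORMALITIES {len(items)}"]
    for i, (name, contour) in enumerate(items, start=1):
        (sx, sy), codes = contour_to_chain(contour)
        out.append(f"ABNORMALITY {i}")
        out.append(f"NAME {name}")
        for key, val in meta.get(name, {}).items():
            out.append(f"{key.upper()} {val}")
        out.append("BOUNDARY")
        out.append(" ".join([str(sx), str(sy)] + [str(c) for c in codes] + ["#"]))
    Path(path).write_text("\n".join(out) + "\n")


def read_vertices_csv(path) -> Contour:
    """Read a plain x,y vertex list into a contour (orientation auto-fixed)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"{Path(path).name}: expected columns x,y")
    pts = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    return Contour.from_points(pts, contour_id=Path(path).stem)


def write_vertices_csv(path, contour: Contour) -> None:
    pd.DataFrame(contour.points, columns=["x", "y"]).to_csv(path, index=False)


def read_contour(path, **kwargs) -> Contour:
    """Dispatch on extension: .csv -> vertex list, anything else -> overlay.

    Overlay files with several lesions yield the first lesion block.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_vertices_csv(path)
    return next(iter(read_overlay(path, **kwargs).values()))


def write_signature_csv(path, sig: Signature) -> None:
    """Export a signature: columns index, h, h_p, h_q, theta (1-based index)."""
    n = len(sig)
    nan = np.full(n, np.nan)
    pd.DataFrame(
        {
            "index": np.arange(1, n + 1),
            "h": sig.values,
            "h_p": sig.radial if sig.radial is not None else nan,
            "h_q": sig.ellipse_radius if sig.ellipse_radius is not None else nan,
            "theta": sig.theta if sig.theta is not None else nan,
        }
    ).to_csv(path, index=False)


def write_feature_table_csv(path, table: pd.DataFrame) -> None:
    """Flatten the long-form feature table: id,label,kind,feature,C,v1..vC."""
    c_max = int(table["C"].max())
    rows = []
    for _, row in table.iterrows():
        rec = {k: row[k] for k in ("id", "label", "kind", "feature", "C")}
        for j, v in enumerate(row["values"], start=1):
            rec[f"v{j}"] = v
        rows.append(rec)
    cols = ["id", "label", "kind", "feature", "C"] + [f"v{j}" for j in range(1, c_max + 1)]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def read_manifest(path) -> dict[str, str]:
    """Manifest JSON -> id -> label mapping."""
    records = json.loads(Path(path).read_text())
    return {rec["id"]: rec["label"] for rec in records}


def write_manifest(path, manifest: list[dict]) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1) + "\n")
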