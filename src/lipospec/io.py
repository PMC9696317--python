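"""Spectrum readers/writers and configuration plumbing.

Two dialects are supported: two-column CSV (wavenumber, absorbance; comma
separator, dot decimal, header auto-detected) and JCAMP-DX with
AFFN/fixed-point ``##XYDATA=(X++(Y..Y))`` blocks.  FTIR instruments commonly
write descending wavenumber axes; those are reversed to ascending with a log
note.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import Spectrum

log = logging.getLogger("lipospec")


def read_spectrum(path: str | Path, dialect: str = "csv") -> Spectrum:
    """Read and validate a spectrum from ``path``.

    ``dialect`` is ``'csv'`` or ``'jcamp'``.  Files with NaN rows, fewer than
    two columns or a non-monotone axis are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        wn, ab = _read_csv(path)
    elif dialect == "jcamp":
        wn, ab = _read_jcamp(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if wn.size and wn[0] > wn[-1]:
        log.info("%s: descending wavenumber axis reversed to ascending", path.name)
        wn, ab = wn[::-1], ab[::-1]
    return Spectrum(wn, ab)


def _read_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    # header auto-detection: if the first row does not parse as numbers,
    # treat it as a header
    first = pd.read_csv(path, nrows=1, header=None)
    try:
        first.astype(float)
        header = None
    except (ValueError, TypeError):
        header = 0
    df = pd.read_csv(path, header=header)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, absorbance)")
    df = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        row = int(bad[0]) + (2 if header == 0 else 1)  # 1-based file row
        raise ValueError(f"{path}: non-numeric or NaN value at row {row}")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def _read_jcamp(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: AFFN / fixed-point (X++(Y..Y)) tables only.

    Compressed ordinate forms (DIF/DUP/SQZ/PAC) are rejected with a clear
    message.
    """
    text = path.read_text()
    meta: dict[str, str] = {}
    ys: list[float] = []
    in_table = False
    for raw in text.splitlines():
        line = raw.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                if "X++" not in val.replace(" ", ""):
                    raise ValueError(f"{path}: unsupported XYDATA form {val.strip()!r}")
                in_table = True
                continue
            if key == "END":
                in_table = False
            meta[key] = val.strip()
            continue
        if in_table:
            tokens = line.replace(",", " ").split()
            for tok in tokens[1:]:  # first token is the line's X value
                try:
                    ys.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-AFFN ordinate {tok!r} (compressed JCAMP forms are not supported)"
                    ) from None
    if not ys:
        raise ValueError(f"{path}: no XYDATA table found")
    firstx = float(meta.get("FIRSTX", "nan"))
    lastx = float(meta.get("LASTX", "nan"))
    npoints = int(float(meta.get("NPOINTS", len(ys))))
    if npoints != len(ys):
        raise ValueError(f"{path}: NPOINTS={npoints} but {len(ys)} ordinates read")
    xfactor = float(meta.get("XFACTOR", "1"))
    yfactor = float(meta.get("YFACTOR", "1"))
    if np.isnan(firstx) or np.isnan(lastx):
        raise ValueError(f"{path}: FIRSTX/LASTX missing")
    x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    y = np.asarray(ys) * yfactor
    return x, y


def write_spectrum(s: Spectrum, path: str | Path, dialect: str = "csv") -> None:
    """Write a spectrum as two-column CSV or minimal JCAMP-DX."""
    path = Path(path)
    if dialect == "csv":
        pd.DataFrame(
            {"wavenumber_cm-1": s.wavenumbers, "absorbance": s.absorbance}
        ).to_csv(path, index=False, float_format="%.10g")
    elif dialect == "jcamp":
        lines = [
            "##TITLE=lipospec spectrum",
            "##JCAMP-DX=4.24",
            "##DATATYPE=INFRARED SPECTRUM",
            "##XUNITS=1/CM",
            "##YUNITS=ABSORBANCE",
            "##XFACTOR=1",
            "##YFACTOR=1",
            f"##FIRSTX={s.wavenumbers[0]:.6f}",
            f"##LASTX={s.wavenumbers[-1]:.6f}",
            f"##NPOINTS={len(s)}",
            "##XYDATA=(X++(Y..Y))",
        ]
        for wn, ab in zip(s.wavenumbers, s.absorbance):
            lines.append(f"{wn:.4f} {ab:.10g}")
        lines.append("##END=")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_config(path: str | Path) -> dict:
    """Read a YAML config file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
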