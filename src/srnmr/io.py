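"""Text formats: NMR-STAR-subset shift loops, Sparky-style peak lists, TSV.

Only small, documented dialects of the field's standard text formats are
supported:

* **Shift tables** — a minimal NMR-STAR atom-shift loop
  (``loop_`` / ``_Atom_chem_shift.*`` tags / ``stop_``) restricted to
  backbone atoms N, H, CA, CB, plus a plain TSV mirror of the table.
* **Peak lists** — Sparky-style ``.list`` with an ``Assignment`` label
  followed by one column per dimension (w1 = ¹³C, w2 = ¹⁵N, w3 = ¹H for
  3D; w1 = ¹⁵N, w2 = ¹H for 2D), three decimals, plus a full-fidelity
  TSV mirror.

All writers round-trip losslessly at the documented precision
(3 decimals ppm for shift values in the STAR/Sparky dialects).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .shifts import Peak, ShiftTable

__all__ = [
    "ParseError",
    "write_star",
    "read_star",
    "write_shift_tsv",
    "read_shift_tsv",
    "write_sparky",
    "read_sparky",
    "write_peaks_tsv",
    "read_peaks_tsv",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

_STAR_TAGS = (
    "_Atom_chem_shift.Comp_index_ID",
    "_Atom_chem_shift.Comp_ID",
    "_Atom_chem_shift.Atom_ID",
    "_Atom_chem_shift.Val",
)
_ATOM_COLS = {"N": "n_ppm", "H": "h_ppm", "CA": "ca_ppm", "CB": "cb_ppm"}


class ParseError(ValueError):
    """Malformed input file; message carries the 1-based line number."""


def write_star(table: ShiftTable, path) -> None:
    lines = ["loop_"] + [f"  {t}" for t in _STAR_TAGS] + [""]
    for _, row in table.frame.iterrows():
        comp = _ONE_TO_THREE[row["res_type"]]
        for atom, col in _ATOM_COLS.items():
            val = row[col]
            if isinstance(val, float) and math.isnan(val):
                continue
            lines.append(f"  {int(row['res_index'])} {comp} {atom} {val:.3f}")
    lines += ["stop_", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_star(path) -> ShiftTable:
    with open(path) as fh:
        raw = fh.readlines()
    tags: list[str] = []
    rows: list[tuple[int, str, str, float]] = []
    state = "preamble"
    for lineno, line in enumerate(raw, start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        if state == "preamble":
            if text == "loop_":
                state = "tags"
            continue
        if state == "tags":
            if text.startswith("_"):
                tags.append(text)
                continue
            if list(tags) != list(_STAR_TAGS):
                raise ParseError(
                    f"line {lineno}: unexpected tag set {tags}; this reader "
                    f"supports exactly {list(_STAR_TAGS)}"
                )
            state = "data"
        if state == "data":
            if text == "stop_":
                state = "done"
                continue
            parts = text.split()
            if len(parts) != 4:
                raise ParseError(f"line {lineno}: expected 4 fields, got {len(parts)}")
            idx, comp, atom, val = parts
            try:
                rows.append((int(idx), comp.upper(), atom.upper(), float(val)))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    if state != "done":
        raise ParseError(f"line {len(raw)}: file ended before 'stop_' (truncated?)")
    if not rows:
        raise ParseError("line 1: no shift rows found")
    records: dict[int, dict] = {}
    for idx, comp, atom, val in rows:
        if comp not in _THREE_TO_ONE:
            raise ParseError(f"unknown residue type {comp!r} at residue {idx}")
        rec = records.setdefault(
            idx,
            {
                "res_index": idx,
                "res_type": _THREE_TO_ONE[comp],
                "n_ppm": math.nan,
                "h_ppm": math.nan,
                "ca_ppm": math.nan,
                "cb_ppm": math.nan,
            },
        )
        if atom in _ATOM_COLS:
            rec[_ATOM_COLS[atom]] = val
    frame = pd.DataFrame.from_records(
        [records[i] for i in sorted(records)]
    ).reset_index(drop=True)
    return ShiftTable(frame)


def write_shift_tsv(table: ShiftTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_shift_tsv(path) -> ShiftTable:
    frame = pd.read_csv(path, sep="\t")
    required = {"res_index", "res_type", "n_ppm", "h_ppm", "ca_ppm", "cb_ppm"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"line 1: missing column(s) {sorted(missing)}")
    return ShiftTable(frame)


def _assignment_label(p: Peak) -> str:
    i = p.truth[0]
    if p.c_ppm is None:
        return f"R{i}N-H"
    j = p.truth[1]
    atom = p.c_atom or "CA"
    return f"R{j}{atom}-R{i}N-R{i}H"


def write_sparky(peaks: list[Peak], path) -> None:
    """Write a Sparky-style .list (w1=13C, w2=15N, w3=1H for 3D peaks)."""
    three_d = any(p.c_ppm is not None for p in peaks)
    with open(path, "w") as fh:
        if three_d:
            fh.write(f"{'Assignment':>20} {'w1':>9} {'w2':>9} {'w3':>9}\n\n")
            for p in peaks:
                if p.c_ppm is None:
                    continue
                fh.write(
                    f"{_assignment_label(p):>20} {p.c_ppm:9.3f} {p.n_ppm:9.3f} "
                    f"{p.h_ppm:9.3f}\n"
                )
        else:
            fh.write(f"{'Assignment':>20} {'w1':>9} {'w2':>9}\n\n")
            for p in peaks:
                fh.write(f"{_assignment_label(p):>20} {p.n_ppm:9.3f} {p.h_ppm:9.3f}\n")


def read_sparky(path) -> pd.DataFrame:
    """Read the documented Sparky dialect into a DataFrame of label + w columns."""
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("Assignment"):
                continue
            parts = text.split()
            if ncols is None:
                ncols = len(parts)
            if len(parts) != ncols:
                raise ParseError(f"line {lineno}: expected {ncols} fields")
            try:
                rows.append([parts[0]] + [float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    if not rows:
        raise ParseError("line 1: empty peak list")
    cols = ["assignment"] + [f"w{k}" for k in range(1, ncols)]
    return pd.DataFrame(rows, columns=cols)


_PEAK_COLS = [
    "experiment", "h_ppm", "n_ppm", "c_ppm", "intensity", "c_fwhm_hz",
    "fine_structure", "j_hz", "strip_residue", "carbon_residue", "c_atom",
]


def write_peaks_tsv(peaks: list[Peak], path) -> None:
    rows = []
    for p in peaks:
        rows.append(
            {
                "experiment": p.experiment,
                "h_ppm": p.h_ppm,
                "n_ppm": p.n_ppm,
                "c_ppm": p.c_ppm if p.c_ppm is not None else np.nan,
                "intensity": p.intensity,
                "c_fwhm_hz": p.c_fwhm_hz if p.c_fwhm_hz is not None else np.nan,
                "fine_structure": p.fine_structure,
                "j_hz": p.j_hz if p.j_hz is not None else np.nan,
                "strip_residue": p.truth[0],
                "carbon_residue": p.truth[1] if len(p.truth) > 1 else -1,
                "c_atom": p.c_atom or "",
            }
        )
    pd.DataFrame(rows, columns=_PEAK_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_peaks_tsv(path) -> list[Peak]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_PEAK_COLS) - set(frame.columns)
    if missing:
        raise ParseError(f"line 1: missing column(s) {sorted(missing)}")
    peaks = []
    for _, r in frame.iterrows():
        c = None if math.isnan(r["c_ppm"]) else float(r["c_ppm"])
        truth = (
            (int(r["strip_residue"]),)
            if int(r["carbon_residue"]) < 0
            else (int(r["strip_residue"]), int(r["carbon_residue"]))
        )
        peaks.append(
            Peak(
                experiment=r["experiment"],
                h_ppm=float(r["h_ppm"]),
                n_ppm=float(r["n_ppm"]),
                c_ppm=c,
                intensity=float(r["intensity"]),
                c_fwhm_hz=None if math.isnan(r["c_fwhm_hz"]) else float(r["c_fwhm_hz"]),
                fine_structure=r["fine_structure"],
                j_hz=None if math.isnan(r["j_hz"]) else float(r["j_hz"]),
                truth=truth,
                c_atom=(r["c_atom"] if isinstance(r["c_atom"], str) and r["c_atom"] else None),
            )
        )
    return peaks
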