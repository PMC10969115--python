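"""Reading and writing pmf tables and measure reports.

A pmf table is a delimited text file (TSV by default, CSV accepted) with one
header row of variable names plus a final probability column, and one row per
outcome.  Probabilities may be decimals or exact fractions ("1/4"); symbols
are parsed as ints when possible, tuples when written like "(0, 1)", and kept
as strings otherwise.  Unlisted outcomes carry zero mass.
"""

from __future__ import annotations

import ast
import hashlib
import json
from fractions import Fraction
from pathlib import Path

import numpy as np

from .discrete import JointPMF, _marginal_array

__all__ = ["read_pmf", "write_pmf", "write_report", "REPORT_SCHEMA"]

#: informal JSON-report schema, shipped for validation in tests and by users
REPORT_SCHEMA = {
    "type": "object",
    "required": ["tool", "version", "results"],
    "properties": {
        "tool": {"type": "string"},
        "version": {"type": "string"},
        "input_digest": {"type": ["string", "null"]},
        "results": {"type": "array"},
    },
}


def _parse_symbol(text: str):
    text = text.strip()
    try:
        return int(text)
    except ValueError:
        pass
    if text.startswith("("):
        try:
            value = ast.literal_eval(text)
            if isinstance(value, tuple):
                return value
        except (ValueError, SyntaxError):
            pass
    return text


def _parse_mass(text: str) -> float:
    text = text.strip()
    if "/" in text:
        return float(Fraction(text))
    return float(text)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_pmf(
    path: str | Path,
    target: str | None = None,
    renormalize: bool = False,
) -> JointPMF:
    """Read a pmf table; the last column is the probability.

    Raises ``ValueError`` on negative masses, duplicate outcome rows, or a
    total differing from 1 by more than 1e-6 (unless ``renormalize``).
    """
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty pmf table")
    delim = _sniff_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(delim)]
    if len(header) < 2:
        raise ValueError(f"{path}: need at least one variable and a probability column")
    variables = tuple(header[:-1])
    outcomes: dict[tuple, float] = {}
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(delim)]
        if len(cells) != len(header):
            raise ValueError(f"{path}: row has {len(cells)} cells, expected {len(header)}")
        key = tuple(_parse_symbol(c) for c in cells[:-1])
        mass = _parse_mass(cells[-1])
        if mass < 0:
            raise ValueError(f"{path}: negative mass {mass} for outcome {key}")
        if key in outcomes:
            raise ValueError(f"{path}: duplicate outcome row {key}")
        outcomes[key] = mass
    total = sum(outcomes.values())
    if abs(total - 1.0) > 1e-6:
        if not renormalize:
            raise ValueError(f"{path}: masses sum to {total}, not 1")
        outcomes = {k: v / total for k, v in outcomes.items()}
    if target is not None and target not in variables:
        raise ValueError(f"{path}: target {target!r} not among columns {variables}")
    return JointPMF.from_outcomes(variables, outcomes, target=target)


def _format_symbol(sym) -> str:
    if isinstance(sym, tuple):
        return "(" + ", ".join(str(s) for s in sym) + ")"
    return str(sym)


def pmf_to_text(pmf: JointPMF, delimiter: str = "\t") -> str:
    """Positive-mass rows in canonical order (target first, sources in
    declaration order; rows lexicographic in alphabet indices)."""
    order = ((pmf.target,) if pmf.target else ()) + tuple(
        v for v in pmf.variables if v != pmf.target
    )
    arr = _marginal_array(pmf, order)
    lines = [delimiter.join(order + ("p",))]
    for idx in np.ndindex(arr.shape):
        mass = arr[idx]
        if mass <= 0:
            continue
        syms = [_format_symbol(pmf.alphabets[v][i]) for v, i in zip(order, idx)]
        lines.append(delimiter.join(syms + [repr(float(mass))]))
    return "\n".join(lines) + "\n"


def write_pmf(pmf: JointPMF, path: str | Path, delimiter: str = "\t") -> None:
    Path(path).write_text(pmf_to_text(pmf, delimiter))


def pmf_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_report(
    results: list[dict],
    path: str | Path | None,
    format: str = "json",
    input_digest: str | None = None,
) -> str:
    """Serialize measure results (with tool version and input digest).

    ``results`` is a list of {"measure": ..., "value": ..., ...} records;
    returns the serialized text and writes it when ``path`` is given.
    """
    from . import __version__

    if format == "json":
        doc = {
            "tool": "unionpid",
            "version": __version__,
            "input_digest": input_digest,
            "results": results,
        }
        text = json.dumps(doc, indent=2, default=_jsonify) + "\n"
    elif format == "tsv":
        keys = sorted({k for r in results for k in r})
        lines = ["\t".join(keys)]
        for r in results:
            lines.append("\t".join(_tsvify(r.get(k, "")) for k in keys))
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown report format {format!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def _jsonify(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


def _tsvify(value) -> str:
    if isinstance(value, float):
        return f"{value:.9g}"
    return str(value)
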