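"""Minimal FCS 3.0/3.1 reading and writing.

Supports list-mode files with float32 (``$DATATYPE/F``), float64 (``D``)
or unsigned-integer (``I``, 8/16/32/64-bit) data in either byte order.
This covers the files the pipeline itself writes and the common output of
mass/spectral cytometry acquisition software after preprocessing.

Analysis segments, supplemental text and multi-dataset files
(``$NEXTDATA`` > 0) are not interpreted.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_fcs", "write_fcs"]

_DELIM = "/"


class FCSError(ValueError):
    """Raised when a file violates the FCS structure this reader supports."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    inner = body[1:]
    end = inner.rfind(delim)
    if end < 0:
        raise FCSError("TEXT segment lacks a closing delimiter")
    if inner[end + 1 :].strip():
        raise FCSError("unexpected bytes after final TEXT delimiter")
    parts = inner[:end].split(delim)
    # A delimiter inside a value is escaped by doubling, which splits into an
    # empty part; merge those back.
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 2 < len(parts) and parts[i + 1] == "":
            tok += delim + parts[i + 2]
            i += 2
        tokens.append(tok)
        i += 1
    if len(tokens) % 2:
        raise FCSError("odd number of TEXT tokens")
    return {tokens[j].strip(): tokens[j + 1] for j in range(0, len(tokens), 2)}


def read_fcs(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an FCS file into an events x channels DataFrame.

    Returns ``(data, text)`` where ``data`` columns are the ``$PnN`` channel
    names and ``text`` is the raw TEXT keyword dictionary.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FCSError(f"{path}: file too short for an FCS header")
    version = blob[:6].decode("latin-1")
    if not version.startswith("FCS"):
        raise FCSError(f"{path}: not an FCS file (version field {version!r})")
    try:
        text_begin = int(blob[10:18])
        text_end = int(blob[18:26])
        data_begin = int(blob[26:34])
        data_end = int(blob[34:42])
    except ValueError as exc:
        raise FCSError(f"{path}: malformed header offsets") from exc

    text = _parse_text_segment(blob[text_begin : text_end + 1])

    # Large files put 0 in the header and the real offsets in TEXT.
    if data_begin == 0:
        data_begin = int(text["$BEGINDATA"])
    if data_end == 0:
        data_end = int(text["$ENDDATA"])

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text["$DATATYPE"].strip().upper()
    byteord = text["$BYTEORD"].strip()
    little = byteord.startswith("1")
    order = "<" if little else ">"

    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]

    if datatype == "F":
        dtype = np.dtype(f"{order}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{order}f8")
    elif datatype == "I":
        bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1:
            raise FCSError(f"{path}: mixed $PnB widths unsupported")
        width = bits.pop()
        if width not in (8, 16, 32, 64):
            raise FCSError(f"{path}: unsupported integer width {width}")
        dtype = np.dtype(f"{order}u{width // 8}")
    else:
        raise FCSError(f"{path}: unsupported $DATATYPE {datatype!r}")

    raw = blob[data_begin : data_end + 1]
    expected = n_tot * n_par * dtype.itemsize
    if len(raw) < expected:
        raise FCSError(
            f"{path}: DATA segment holds {len(raw)} bytes, "
            f"expected {expected} for {n_tot} x {n_par}"
        )
    values = np.frombuffer(raw[:expected], dtype=dtype).reshape(n_tot, n_par)
    data = pd.DataFrame(np.asarray(values, dtype=np.float64), columns=names)
    return data, text


def write_fcs(path: str | Path, data: pd.DataFrame, extra_text: dict[str, str] | None = None) -> None:
    """Write an events x channels DataFrame as FCS 3.1, float32 list mode."""
    path = Path(path)
    n_tot, n_par = data.shape
    payload = np.ascontiguousarray(data.to_numpy(dtype=np.float32))

    keywords: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$TOT": str(n_tot),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(data.columns, start=1):
        col = payload[:, i - 1]
        rng = float(col.max(initial=0.0))
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)
    if extra_text:
        keywords.update(extra_text)

    header_len = 58
    # Two-pass layout: TEXT length depends on the offset digits, which are
    # written with fixed width so a single extra pass suffices.
    def render_text(data_begin: int, data_end: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(data_begin)
        kw["$ENDDATA"] = str(data_end)
        parts = [_DELIM]
        for key, value in kw.items():
            value = str(value).replace(_DELIM, _DELIM * 2) or " "
            parts.append(f"{key}{_DELIM}{value}{_DELIM}")
        return "".join(parts).encode("latin-1")

    text = render_text(0, 0)
    # Reserve 10 digits for each offset; recompute with real values.
    probe = render_text(9_999_999_999, 9_999_999_999)
    text_begin = header_len
    text_end = text_begin + len(probe) - 1
    data_begin = text_end + 1
    data_end = data_begin + payload.nbytes - 1
    text = render_text(data_begin, data_end)
    text = text.ljust(len(probe), b" ")

    def fmt(value: int) -> bytes:
        s = str(value)
        if len(s) > 8:
            s = "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_begin) + fmt(text_end)
    header += fmt(data_begin if data_begin <= 99_999_999 else 0)
    header += fmt(data_end if data_end <= 99_999_999 else 0)
    header += fmt(0) + fmt(0)
    assert len(header) == header_len, len(header)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload.tobytes())
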