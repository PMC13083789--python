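"""Minimal FCS 3.0/3.1 list-mode reader.

Supports the subset the pipeline needs: uncompressed list-mode ($MODE L)
files with floating-point ($DATATYPE F or D) or plain integer ($DATATYPE I,
8/16/32/64-bit, no bit masking) data, little- or big-endian.  FCS 2.0,
correlated/uncorrelated histogram modes, ASCII data and bit-packed
integers are out of scope.  Returns channel names and the raw event
matrix; keyword text is passed back for provenance.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError

_HEADER_LEN = 58


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    """Decode the TEXT segment: delimiter-separated key/value pairs.

    A doubled delimiter inside a value is an escaped literal delimiter
    (FCS 3.1 §3.2.8); empty keywords are not allowed.
    """
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # split on single delimiters; a doubled delimiter yields an empty token,
    # which re-joins its neighbours with one literal delimiter
    parts = body.split(delim)
    tokens: list[bytes] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == b"":
            nxt = parts[i + 2] if i + 2 < len(parts) else b""
            tok = tok + delim + nxt
            i += 2
        tokens.append(tok)
        i += 1
    if len(tokens) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of tokens")
    keywords = {}
    for k, v in zip(tokens[0::2], tokens[1::2]):
        keywords[k.decode("utf-8", errors="replace").strip().upper()] = v.decode(
            "utf-8", errors="replace"
        )
    return keywords


def read_fcs(path) -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Read an FCS 3.0/3.1 list-mode file.

    Returns ``(channel_names, events, keywords)`` where ``events`` is an
    ``(n_events, n_channels)`` float array.  Channel names prefer the stain
    name ``$PnS`` and fall back to the short name ``$PnN``.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < _HEADER_LEN:
        raise FormatError("file too short to hold an FCS header")
    version = data[0:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"unsupported FCS version {version!r} (need FCS3.0/3.1)")

    def _offset(a: int, b: int) -> int:
        txt = data[a:b].decode("ascii", errors="replace").strip()
        return int(txt) if txt else 0

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    kw = _parse_text_segment(data[text_begin : text_end + 1])

    if kw.get("$MODE", "L").upper() != "L":
        raise FormatError(f"unsupported $MODE {kw.get('$MODE')!r} (need list mode L)")
    datatype = kw.get("$DATATYPE", "").upper()
    if datatype not in ("F", "D", "I"):
        raise FormatError(
            f"unsupported $DATATYPE {kw.get('$DATATYPE')!r} (need F, D or I)"
        )
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
    except KeyError as exc:
        raise FormatError(f"missing required keyword {exc.args[0]}") from None

    # data segment offsets may live in the header or in $BEGINDATA/$ENDDATA
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    if data_begin <= 0:
        raise FormatError("cannot locate the DATA segment")

    byteord = kw.get("$BYTEORD", "1,2,3,4")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FormatError(f"unsupported $BYTEORD {byteord!r}")

    bits = []
    names = []
    for i in range(1, n_par + 1):
        try:
            bits.append(int(kw[f"$P{i}B"]))
        except KeyError:
            raise FormatError(f"missing keyword $P{i}B") from None
        name = kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}"
        names.append(name)

    if datatype == "F":
        expected_bits = {32}
    elif datatype == "D":
        expected_bits = {64}
    else:
        expected_bits = {8, 16, 32, 64}
    for i, b in enumerate(bits, start=1):
        if b not in expected_bits:
            raise FormatError(
                f"$P{i}B={b} unsupported for $DATATYPE {datatype} "
                f"(supported: {sorted(expected_bits)})"
            )
    if datatype == "I" and len(set(bits)) > 1:
        raise FormatError("mixed integer widths per event are not supported")

    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    else:
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")

    nbytes = n_par * n_tot * dtype.itemsize
    raw = data[data_begin : data_begin + nbytes]
    if len(raw) < nbytes:
        raise FormatError(
            f"DATA segment truncated: need {nbytes} bytes, found {len(raw)}"
        )
    events = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(float)
    return names, events, kw
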