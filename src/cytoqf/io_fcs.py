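"""Event-level I/O and display-scale transforms.

Cytometry events live in FCS container files (binary, self-describing via a
keyword TEXT segment) or, for interchange and fixtures, in plain CSV tables
with one header row of channel names.  Fluorescence channels are usually
displayed and clustered on the Logicle scale, a biexponential that is
logarithmic at high signal, linear through zero, and accommodates the
negative values produced by compensation.

This module reads FCS 2.0/3.0/3.1, writes FCS 3.1 (float data), and provides
the Logicle transform and its inverse.  No compensation is applied: input is
assumed compensated upstream.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    EmptyInputError,
    FormatError,
    ParameterError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EventMatrix",
    "LogicleParams",
    "read_fcs",
    "write_fcs",
    "read_csv_events",
    "write_csv_events",
    "read_labels",
    "write_labels",
    "logicle",
    "logicle_inverse",
    "estimate_w",
    "apply_logicle",
]

#: channel-name patterns treated as non-fluorescence (linear) by default
SCATTER_PATTERN = re.compile(r"^(fsc|ssc)|^time$", re.IGNORECASE)


@dataclass
class EventMatrix:
    """Events x channels table with per-channel transform state.

    ``transformed[j]`` is one of ``"raw"``, ``"logicle"`` or ``"linear"``
    (linear passthrough rescaling used for scatter/time channels).
    """

    values: np.ndarray
    channel_names: list[str]
    transformed: list[str] = field(default_factory=list)
    sample_id: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("event matrix must be 2-dimensional")
        if len(self.channel_names) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.values.shape[1]} columns"
            )
        if not self.transformed:
            self.transformed = ["raw"] * self.values.shape[1]
        if len(self.transformed) != self.values.shape[1]:
            raise ValidationError("transformed flags do not match columns")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def drop_nonfinite(self) -> "EventMatrix":
        """Return a copy with rows containing non-finite values removed."""
        keep = np.isfinite(self.values).all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info(
                "dropped %d event rows with non-finite values (sample %s)",
                dropped,
                self.sample_id or "<unnamed>",
            )
        return replace(
            self,
            values=self.values[keep],
            n_dropped=self.n_dropped + dropped,
        )


# ---------------------------------------------------------------------------
# Logicle transform
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogicleParams:
    """Parameters of the Logicle display scale.

    T  top-of-scale data value (display hits M decades at x = T)
    M  total display width in decades
    W  linearization width in decades around zero
    A  additional negative display decades below zero
    """

    T: float = 262144.0
    M: float = 4.5
    W: float = 0.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ParameterError("T must be > 0")
        if not (self.M > 0):
            raise ParameterError("M must be > 0")
        if not (0 <= self.W <= self.M / 2):
            raise ParameterError("W must satisfy 0 <= W <= M/2")
        if self.A < 0:
            raise ParameterError("A must be >= 0")


def _logicle_coefficients(p: LogicleParams) -> dict:
    """Biexponential coefficients for the (T, W, M, A) parameterization.

    The scale variable y runs over [0, 1]; display value = (M + A) * y - A,
    so y = 1 maps to M display decades.  The biexponential inverse is
    B(y) = a*exp(b*y) - c*exp(-d*y) + f with B(x1) = 0 and B(1) = T.
    """
    span = p.M + p.A
    w = p.W / span
    x2 = p.A / span
    x1 = x2 + w
    x0 = x2 + 2.0 * w
    b = span * math.log(10.0)
    if w <= 0:
        d = b
    else:
        # d solves 2(ln d - ln b) + w(b + d) = 0 on (0, b)
        d = brentq(
            lambda t: 2.0 * (math.log(t) - math.log(b)) + w * (b + t),
            1e-12 * b,
            b,
            xtol=1e-15,
            rtol=8.9e-16,
        )
    c_a = math.exp(x0 * (b + d))
    mf_a = math.exp(b * x1) - c_a / math.exp(d * x1)
    a = p.T / ((math.exp(b) - mf_a) - c_a / math.exp(d))
    return {"a": a, "b": b, "c": c_a * a, "d": d, "f": -mf_a * a, "x1": x1, "span": span, "A": p.A}


def _biexponential(y: np.ndarray, co: dict) -> np.ndarray:
    return co["a"] * np.exp(co["b"] * y) - co["c"] * np.exp(-co["d"] * y) + co["f"]


def logicle_inverse(v, params: LogicleParams = LogicleParams()):
    """Map display values (decades) back to data values (biexponential)."""
    co = _logicle_coefficients(params)
    v = np.asarray(v, dtype=np.float64)
    y = (v + co["A"]) / co["span"]
    out = _biexponential(y, co)
    return float(out) if out.ndim == 0 else out


def logicle(x, params: LogicleParams = LogicleParams()):
    """Logicle display transform of data value(s) x.

    Strictly monotone; logicle(T) = M; smooth/linear through zero.  Computed
    by inverting the biexponential with a vectorized bisection (the
    biexponential is strictly increasing everywhere).
    """
    co = _logicle_coefficients(params)
    x = np.asarray(x, dtype=np.float64)
    scalar = x.ndim == 0
    xf = np.atleast_1d(x).astype(np.float64)

    lo = np.full_like(xf, co["x1"] - 1.0)
    hi = np.full_like(xf, 1.0 + 1e-9)
    # expand brackets until B(lo) <= x <= B(hi) elementwise
    for _ in range(200):
        bad = _biexponential(lo, co) > xf
        if not bad.any():
            break
        lo[bad] -= 1.0
    for _ in range(200):
        bad = _biexponential(hi, co) < xf
        if not bad.any():
            break
        hi[bad] += 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        below = _biexponential(mid, co) < xf
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    y = 0.5 * (lo + hi)
    out = co["span"] * y - co["A"]
    return float(out[0]) if scalar else out.reshape(x.shape)


def estimate_w(channel_values: np.ndarray, T: float = 262144.0, M: float = 4.5) -> float:
    """Per-channel linearization width from the negative-value tail.

    W = max(0, (M - log10(T/|r|)) / 2) with r the 5th percentile of the
    channel's negative values; defaults to 0.5 decades when the channel has
    no negative events.
    """
    neg = channel_values[channel_values < 0]
    if neg.size == 0:
        return 0.5
    r = abs(np.percentile(neg, 5))
    if r <= 0:
        return 0.5
    w = max(0.0, (M - math.log10(T / r)) / 2.0)
    return min(w, M / 2.0)


def apply_logicle(
    em: EventMatrix,
    channels: list[str] | None = None,
    T: float = 262144.0,
    M: float = 4.5,
    A: float = 0.0,
    W: float | None = None,
    scatter_pattern: re.Pattern = SCATTER_PATTERN,
) -> EventMatrix:
    """Transform fluorescence channels to the Logicle scale.

    Channels matching ``scatter_pattern`` (FSC*/SSC*/Time by default) are
    linearly rescaled to [0, M] instead — those signals are already linear.
    ``W=None`` estimates the width per channel from the negative tail.
    Returns a new EventMatrix with transform flags set for exactly the
    channels transformed.
    """
    if channels is None:
        channels = list(em.channel_names)
    values = em.values.copy()
    flags = list(em.transformed)
    for name in channels:
        j = em.channel_index(name)
        col = values[:, j]
        if scatter_pattern.match(name):
            rng = col.max() - col.min()
            values[:, j] = M * (col - col.min()) / rng if rng > 0 else 0.0
            flags[j] = "linear"
        else:
            w = estimate_w(col, T, M) if W is None else W
            params = LogicleParams(T=T, M=M, W=w, A=A)
            values[:, j] = logicle(col, params)
            flags[j] = "logicle"
    return replace(em, values=values, transformed=flags)


# ---------------------------------------------------------------------------
# FCS container
# ---------------------------------------------------------------------------

_HEADER_LEN = 58


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if len(raw) < 2:
        raise FormatError("TEXT segment too short to contain a delimiter")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    tokens = body.split(delim)
    # doubled delimiters inside values appear as empty tokens
    merged: list[str] = []
    i = 0
    d = delim.decode("latin-1")
    while i < len(tokens):
        t = tokens[i].decode("latin-1")
        while i + 2 < len(tokens) and tokens[i + 1] == b"":
            t += d + tokens[i + 2].decode("latin-1")
            i += 2
        merged.append(t)
        i += 1
    if len(merged) % 2 == 1:
        merged.append("")
    keys = [k.strip().upper() for k in merged[0::2]]
    vals = [v for v in merged[1::2]]
    return dict(zip(keys, vals))


def _require(text: dict[str, str], key: str) -> str:
    if key not in text:
        raise FormatError(f"required FCS keyword {key} missing")
    return text[key]


def read_fcs(path) -> EventMatrix:
    """Read an FCS 2.0/3.0/3.1 file into an EventMatrix.

    Channel names come from $PnN with $PnS fallback.  Rows containing
    non-finite values are dropped (count logged and recorded).
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FormatError("file shorter than an FCS HEADER segment")
    version = raw[0:6].decode("latin-1")
    if version not in ("FCS2.0", "FCS3.0", "FCS3.1"):
        raise FormatError(f"unsupported FCS version field {version!r}")

    def _offset(a: int, b: int) -> int:
        s = raw[a:b].decode("latin-1").strip()
        return int(s) if s else 0

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    if text_end <= text_begin or text_end >= len(raw):
        raise FormatError("invalid TEXT offsets in HEADER")
    text = _parse_text_segment(raw[text_begin : text_end + 1])

    if data_begin == 0 or data_end == 0:
        data_begin = int(_require(text, "$BEGINDATA"))
        data_end = int(_require(text, "$ENDDATA"))

    par = int(_require(text, "$PAR"))
    tot = int(_require(text, "$TOT"))
    if tot == 0:
        raise EmptyInputError("FCS file contains zero events ($TOT=0)")
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FormatError(f"unsupported $MODE {mode!r} (list mode only)")
    datatype = _require(text, "$DATATYPE").upper()
    byteord = _require(text, "$BYTEORD")
    if byteord.startswith("1"):
        order = "<"
    elif byteord.startswith("4") or byteord in ("2,1",):
        order = ">"
    else:
        raise FormatError(f"unsupported $BYTEORD {byteord!r}")

    bits = [int(_require(text, f"$P{n}B")) for n in range(1, par + 1)]
    if datatype == "F":
        dtypes = [np.dtype(order + "f4")] * par
    elif datatype == "D":
        dtypes = [np.dtype(order + "f8")] * par
    elif datatype == "I":
        dtypes = []
        for b in bits:
            if b not in (8, 16, 32, 64):
                raise FormatError(f"unsupported integer $PnB width {b}")
            dtypes.append(np.dtype(order + f"u{b // 8}"))
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")

    row_bytes = sum(dt.itemsize for dt in dtypes)
    payload = raw[data_begin : data_end + 1]
    if len(payload) < row_bytes * tot:
        raise FormatError(
            "$ENDDATA inconsistent with $TOT/$PAR: DATA segment truncated"
        )
    payload = payload[: row_bytes * tot]
    if len(set(dtypes)) == 1:
        values = np.frombuffer(payload, dtype=dtypes[0]).reshape(tot, par)
        values = values.astype(np.float64)
    else:
        rec = np.frombuffer(
            payload, dtype=np.dtype([(f"c{i}", dt) for i, dt in enumerate(dtypes)])
        )
        values = np.column_stack([rec[f"c{i}"].astype(np.float64) for i in range(par)])

    names = []
    for n in range(1, par + 1):
        names.append(text.get(f"$P{n}N") or text.get(f"$P{n}S") or f"P{n}")

    em = EventMatrix(
        values=values,
        channel_names=names,
        sample_id=text.get("$FIL", path.stem),
    )
    return em.drop_nonfinite()


def write_fcs(em: EventMatrix, path) -> Path:
    """Write an EventMatrix as an FCS 3.1 list-mode file (float32 data)."""
    if em.n_events == 0:
        raise EmptyInputError("refusing to write an FCS file with zero events")
    path = Path(path)
    data = np.ascontiguousarray(em.values, dtype="<f4").tobytes()

    delim = "/"
    kw: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "%012d"),
        ("$ENDDATA", "%012d"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(em.n_channels)),
        ("$TOT", str(em.n_events)),
        ("$FIL", em.sample_id or path.name),
    ]
    for j, name in enumerate(em.channel_names, start=1):
        finite_max = float(np.nanmax(np.abs(em.values[:, j - 1]))) if em.n_events else 1.0
        pnr = max(1, int(math.ceil(finite_max)))
        kw += [
            (f"$P{j}B", "32"),
            (f"$P{j}E", "0,0"),
            (f"$P{j}N", name.replace(delim, delim + delim)),
            (f"$P{j}R", str(pnr)),
        ]

    def render(begin_data: int, end_data: int) -> bytes:
        parts = [delim]
        for k, v in kw:
            if v == "%012d":
                v = "%012d" % (begin_data if k == "$BEGINDATA" else end_data)
            parts += [k, delim, v, delim]
        return "".join(parts).encode("latin-1")

    text = render(0, 0)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    text = render(data_begin, data_end)  # fixed-width offsets: length unchanged

    def fmt(n: int) -> bytes:
        s = str(n) if n <= 99999999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        fmt(v) for v in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    path.write_bytes(header + text + data)
    return path


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def read_csv_events(path, sample_id: str | None = None) -> EventMatrix:
    """Read a comma-separated event table (header row = channel names)."""
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no event rows")
    em = EventMatrix(
        values=df.to_numpy(dtype=np.float64),
        channel_names=[str(c) for c in df.columns],
        sample_id=sample_id or Path(path).stem,
    )
    return em.drop_nonfinite()


def write_csv_events(em: EventMatrix, path) -> Path:
    path = Path(path)
    pd.DataFrame(em.values, columns=em.channel_names).to_csv(path, index=False)
    return path


def read_labels(path, n_events: int | None = None) -> np.ndarray:
    """Read a label CSV (event_index, cluster_id) into a dense label vector.

    cluster_id is an integer >= 1; 0 marks unassigned events.  When
    ``n_events`` is given the file must cover exactly indices 0..n_events-1.
    """
    df = pd.read_csv(path)
    if not {"event_index", "cluster_id"}.issubset(df.columns):
        raise ValidationError(
            f"{path}: label CSV needs columns event_index, cluster_id"
        )
    idx = df["event_index"].to_numpy(dtype=np.int64)
    lab = df["cluster_id"].to_numpy(dtype=np.int64)
    n = n_events if n_events is not None else (idx.max() + 1 if idx.size else 0)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValidationError(
            f"{path}: event_index out of range for {n} events"
        )
    if n_events is not None and idx.size != n_events:
        raise ValidationError(
            f"{path}: {idx.size} label rows for {n_events} events"
        )
    out = np.zeros(n, dtype=np.int64)
    out[idx] = lab
    return out


def write_labels(labels: np.ndarray, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"event_index": np.arange(len(labels)), "cluster_id": labels}
    ).to_csv(path, index=False)
    return path
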