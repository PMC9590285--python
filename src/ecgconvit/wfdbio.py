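"""Minimal reader/writer for the WFDB record dialect (.hea/.dat/.atr).

Supports the subset of the format family that ambulatory ECG archives use:
header files with per-signal format/gain/baseline, signal files in format 16
(little-endian int16) and format 212 (two 12-bit samples packed into three
bytes), and the MIT annotation stream (6-bit type code + 10-bit time
increment words, with SKIP/NUM/SUB/CHN/AUX pseudo-codes).

Only what the beat pipeline needs is implemented; multi-segment records,
checksums and the more exotic signal formats are out of scope.  A writer is
provided so tests and the synthetic generator can round-trip records.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

# MIT annotation code -> display symbol (the standard WFDB code table).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


class WfdbFormatError(ValueError):
    """Raised when a .hea/.dat/.atr file does not parse."""


def read_header(hea_path: str | Path) -> dict:
    """Parse a .hea file into record name, n_sig, fs, n_samp and signal specs."""
    hea_path = Path(hea_path)
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise WfdbFormatError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 3:
        raise WfdbFormatError(f"{hea_path}: malformed record line {lines[0]!r}")
    name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samp = int(head[3]) if len(head) > 3 else None
    signals = []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise WfdbFormatError(f"{hea_path}: malformed signal line {ln!r}")
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, 0
        if len(parts) > 2:
            gain_field = parts[2]
            if "(" in gain_field:
                g, rest = gain_field.split("(")
                baseline = int(rest.split(")")[0])
                gain_field = g
            gain_field = gain_field.split("/")[0]
            gain = float(gain_field) if gain_field else 200.0
        signals.append({"file": parts[0], "fmt": fmt, "gain": gain or 200.0,
                        "baseline": baseline})
    if len(signals) != n_sig:
        raise WfdbFormatError(f"{hea_path}: expected {n_sig} signal lines")
    return {"name": name, "n_sig": n_sig, "fs": fs, "n_samp": n_samp,
            "signals": signals}


def _decode_212(raw: bytes, n_samples: int) -> np.ndarray:
    """Unpack format-212 byte triplets into int16 samples (two per triplet)."""
    if len(raw) % 3:
        raw = raw[: len(raw) - len(raw) % 3]
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3).astype(np.int32)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * len(b), dtype=np.int32)
    out[0::2], out[1::2] = s1, s2
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out[:n_samples]


def _encode_212(samples: np.ndarray) -> bytes:
    s = np.asarray(samples, dtype=np.int32).copy()
    if s.size % 2:
        s = np.append(s, 0)
    s[s < 0] += 4096
    pairs = s.reshape(-1, 2)
    b = np.empty((len(pairs), 3), dtype=np.uint8)
    b[:, 0] = pairs[:, 0] & 0xFF
    b[:, 1] = ((pairs[:, 0] >> 8) & 0x0F) | (((pairs[:, 1] >> 8) & 0x0F) << 4)
    b[:, 2] = pairs[:, 1] & 0xFF
    return b.tobytes()


def read_signal(dat_path: str | Path, header: dict) -> np.ndarray:
    """Read the .dat file as a (n_samples, n_sig) float array in physical units."""
    dat_path = Path(dat_path)
    raw = dat_path.read_bytes()
    n_sig = header["n_sig"]
    fmt = header["signals"][0]["fmt"]
    if any(sig["fmt"] != fmt for sig in header["signals"]):
        raise WfdbFormatError(f"{dat_path}: mixed signal formats are unsupported")
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    elif fmt == 212:
        total = header["n_samp"] * n_sig if header["n_samp"] else (len(raw) // 3) * 2
        flat = _decode_212(raw, total)
    else:
        raise WfdbFormatError(f"{dat_path}: unsupported signal format {fmt}")
    n_frames = len(flat) // n_sig
    adc = flat[: n_frames * n_sig].reshape(n_frames, n_sig)
    phys = np.empty(adc.shape, dtype=float)
    for i, sig in enumerate(header["signals"]):
        phys[:, i] = (adc[:, i] - sig["baseline"]) / sig["gain"]
    return phys


def read_annotations(atr_path: str | Path) -> list[tuple[int, str]]:
    """Decode an MIT annotation file into (sample_index, symbol) pairs.

    Pseudo-annotations (SKIP/NUM/SUB/CHN/AUX) are consumed but not emitted;
    symbols without a table entry raise.
    """
    atr_path = Path(atr_path)
    raw = atr_path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            if i + 4 > len(raw):
                raise WfdbFormatError(f"{atr_path}: truncated SKIP at byte {i - 2}")
            # SKIP interval: 4 bytes, PDP-11 word order (high word first)
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            t += struct.unpack(">i", struct.pack(">HH", hi, lo))[0]
            i += 4
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += delta + (delta & 1)
            continue
        t += delta
        if code not in _CODE_TO_SYMBOL:
            raise WfdbFormatError(f"{atr_path}: unknown annotation code {code} at byte {i - 2}")
        out.append((t, _CODE_TO_SYMBOL[code]))
    return out


def write_record(directory: str | Path, name: str, signal: np.ndarray, fs: float,
                 annotations: list[tuple[int, str]] | None = None,
                 fmt: int = 16, gain: float = 200.0) -> Path:
    """Write a record (.hea + .dat and optionally .atr); returns the header path.

    ``signal`` is (n_samples,) or (n_samples, n_sig) in physical units; it is
    quantized with the given gain.
    """
    directory = Path(directory)
    sig = np.atleast_2d(np.asarray(signal, dtype=float).T).T
    n_samp, n_sig = sig.shape
    adc = np.rint(sig * gain).astype(np.int32)
    flat = adc.reshape(-1)
    dat = directory / f"{name}.dat"
    if fmt == 16:
        dat.write_bytes(flat.astype("<i2").tobytes())
    elif fmt == 212:
        if np.any(np.abs(flat) > 2047):
            raise ValueError("format 212 overflow: samples exceed 12-bit range")
        dat.write_bytes(_encode_212(flat))
    else:
        raise ValueError(f"unsupported write format {fmt}")
    hea = directory / f"{name}.hea"
    lines = [f"{name} {n_sig} {fs:g} {n_samp}"]
    for _ in range(n_sig):
        lines.append(f"{name}.dat {fmt} {gain:g}(0)/mV 12 0 0 0 0 sig")
    hea.write_text("\n".join(lines) + "\n")
    if annotations is not None:
        write_annotations(directory / f"{name}.atr", annotations)
    return hea


def write_annotations(atr_path: str | Path, annotations: list[tuple[int, str]]) -> None:
    """Encode (sample_index, symbol) pairs as an MIT annotation stream."""
    buf = bytearray()
    prev = 0
    for t, symbol in annotations:
        if symbol not in _SYMBOL_TO_CODE:
            raise ValueError(f"symbol {symbol!r} has no MIT annotation code")
        delta = t - prev
        if delta < 0:
            raise ValueError("annotation times must be non-decreasing")
        while delta > 1023:
            # emit a SKIP word followed by a 4-byte interval
            chunk = min(delta, 2 ** 31 - 1)
            buf += struct.pack("<H", _SKIP << 10)
            hi, lo = (chunk >> 16) & 0xFFFF, chunk & 0xFFFF
            buf += struct.pack("<HH", hi, lo)
            delta -= chunk
        buf += struct.pack("<H", (_SYMBOL_TO_CODE[symbol] << 10) | delta)
        prev = t
    buf += struct.pack("<H", 0)
    Path(atr_path).write_bytes(bytes(buf))
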