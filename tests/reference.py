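"""Independent scalar reference implementations used as test oracles.

Everything here is written as plain per-pixel, per-neighbor Python loops,
deliberately sharing no code with the package beyond the documented
conventions (neighbor p at angle 2*pi*p/P counter-clockwise from east,
row offset -R*sin, bilinear interpolation, inclusive >= thresholds,
border of width ceil(R)+1 excluded).
"""

from __future__ import annotations

import math

import numpy as np


def naive_offsets(P: int, R: float) -> list[tuple[float, float]]:
    out = []
    for p in range(P):
        angle = 2.0 * math.pi * p / P
        dr = -R * math.sin(angle)
        dc = R * math.cos(angle)
        if abs(dr - round(dr)) < 1e-9:
            dr = float(round(dr))
        if abs(dc - round(dc)) < 1e-9:
            dc = float(round(dc))
        out.append((dr, dc))
    return out


def naive_bilinear(pixels: np.ndarray, r: float, c: float) -> float:
    r0, c0 = int(math.floor(r)), int(math.floor(c))
    r0 = min(max(r0, 0), pixels.shape[0] - 2)
    c0 = min(max(c0, 0), pixels.shape[1] - 2)
    dr, dc = r - r0, c - c0
    top = pixels[r0, c0] * (1 - dc) + pixels[r0, c0 + 1] * dc
    bot = pixels[r0 + 1, c0] * (1 - dc) + pixels[r0 + 1, c0 + 1] * dc
    return float(top * (1 - dr) + bot * dr)


def naive_center_mean(pixels: np.ndarray, r: int, c: int) -> float:
    total = 0.0
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            total += pixels[r + i, c + j]
    return total / 9.0


def naive_riu2(bits: list[int]) -> int:
    P = len(bits)
    transitions = sum(abs(bits[p] - bits[p - 1]) for p in range(P))
    if transitions <= 2:
        return sum(bits)
    return P + 1


def naive_pack(bits: list[int]) -> int:
    return sum(b << p for p, b in enumerate(bits))


def naive_glld_rasters(
    pixels: np.ndarray, P: int, R: float, mapping: str = "riu2"
) -> dict[str, np.ndarray]:
    """Per-pixel loop computation of the SGLLD/MGLLD/CGLLD/LBP rasters."""
    pixels = np.asarray(pixels, dtype=np.float64)
    n1, n2 = pixels.shape
    b = int(math.ceil(R)) + 1
    offsets = naive_offsets(P, R)
    rows = range(b, n1 - b)
    cols = range(b, n2 - b)

    # pass 1: moduli for the global modulus threshold
    moduli_all = []
    for r in rows:
        for c in cols:
            gc = naive_center_mean(pixels, r, c)
            for dr, dc in offsets:
                moduli_all.append(abs(naive_bilinear(pixels, r + dr, c + dc) - gc))
    c_mod = sum(moduli_all) / len(moduli_all)
    c_level = float(pixels.mean())

    h, w = n1 - 2 * b, n2 - 2 * b
    out = {
        "sglld": np.zeros((h, w), dtype=np.int64),
        "mglld": np.zeros((h, w), dtype=np.int64),
        "cglld": np.zeros((h, w), dtype=np.int64),
        "lbp": np.zeros((h, w), dtype=np.int64),
        "modulus_threshold": c_mod,
        "level_threshold": c_level,
    }
    reduce = naive_riu2 if mapping == "riu2" else naive_pack
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            gc_mean = naive_center_mean(pixels, r, c)
            sign_bits, mod_bits, lbp_bits = [], [], []
            for dr, dc in offsets:
                gp = naive_bilinear(pixels, r + dr, c + dc)
                diff = gp - gc_mean
                sign_bits.append(1 if diff >= 0 else 0)
                mod_bits.append(1 if abs(diff) >= c_mod else 0)
                lbp_bits.append(1 if gp >= pixels[r, c] else 0)
            out["sglld"][i, j] = reduce(sign_bits)
            out["mglld"][i, j] = reduce(mod_bits)
            out["cglld"][i, j] = 1 if gc_mean >= c_level else 0
            out["lbp"][i, j] = reduce(lbp_bits)
    return out


def naive_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise Mann-Whitney AUC: P(s_pos > s_neg) + 0.5 * P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
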