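"""Independent brute-force oracles, kept free of the implementation's code paths."""

import numpy as np


def flood_fill_components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """Connected components of a boolean mask via explicit 8-neighbour flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for sr in range(h):
        for sc in range(w):
            if not mask[sr, sc] or seen[sr, sc]:
                continue
            stack = [(sr, sc)]
            seen[sr, sc] = True
            pixels = []
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            components.append(pixels)
    return components


def bruteforce_crop_count(
    phase: np.ndarray,
    threshold: float,
    crop_size: int = 66,
    area_min: int = 80,
    area_max: int = 600,
) -> int:
    """Number of crops surviving the strict area and border filters.

    Re-derives everything from scratch: flood-fill components, integer-rounded
    centroid, strict area bounds, and the half-open crop window
    [r − s//2, r − s//2 + s).
    """
    h, w = phase.shape
    n = 0
    for pixels in flood_fill_components(phase > threshold):
        area = len(pixels)
        if not (area_min < area < area_max):
            continue
        rows = np.array([p[0] for p in pixels], dtype=np.float64)
        cols = np.array([p[1] for p in pixels], dtype=np.float64)
        r = int(round(float(np.mean(rows))))
        c = int(round(float(np.mean(cols))))
        half = crop_size // 2
        r0, r1 = r - half, r - half + crop_size
        c0, c1 = c - half, c - half + crop_size
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            continue
        n += 1
    return n


def auc_by_pair_enumeration(scores, labels) -> float:
    """AUC as an explicit double loop over positive/negative pairs (ties = 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y != 1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
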