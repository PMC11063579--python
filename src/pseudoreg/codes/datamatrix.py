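"""DataMatrix ECC 200 (square symbols 10x10 .. 26x26, ASCII encodation).

The default vial-label symbology: DataMatrix packs a short ID into the
smallest footprint, which matters on cryotube labels. Implements the
standard diagonal ("utah") codeword placement with its four corner cases,
Reed-Solomon parity over GF(256) with primitive polynomial 0x12D and first
root a^1, the 253-state pad randomization, and the L-finder / alternating
clock-track frame. The decoder inverts every step (frame check, inverse
placement, RS syndrome check, ASCII de-encodation) and serves as the
round-trip oracle in the label tests.
"""

from __future__ import annotations

from .gf256 import GF_DM, rs_encode, rs_syndromes


class DataMatrixError(ValueError):
    pass


# square symbol size -> (data codewords, ecc codewords)
_SIZES = [
    (10, 3, 5),
    (12, 5, 7),
    (14, 8, 10),
    (16, 12, 12),
    (18, 18, 14),
    (20, 22, 18),
    (22, 30, 20),
    (24, 36, 24),
    (26, 44, 28),
]

_PAD = 129


def _ascii_encode(text: str) -> list[int]:
    out: list[int] = []
    i = 0
    while i < len(text):
        if i + 1 < len(text) and text[i].isdigit() and text[i + 1].isdigit():
            out.append(130 + int(text[i : i + 2]))
            i += 2
            continue
        o = ord(text[i])
        if o > 127:
            raise DataMatrixError(f"character {text[i]!r} outside ASCII encodation")
        out.append(o + 1)
        i += 1
    return out


def _pad_codeword(position: int) -> int:
    # 253-state randomization of pad codewords after the first
    v = _PAD + ((149 * position) % 253) + 1
    return v - 254 if v > 254 else v


def _ascii_decode(codewords: list[int]) -> str:
    out: list[str] = []
    i = 0
    while i < len(codewords):
        cw = codewords[i]
        if cw == _PAD:
            break  # explicit pad: rest is randomized padding
        if 1 <= cw <= 128:
            out.append(chr(cw - 1))
        elif 130 <= cw <= 229:
            out.append(f"{cw - 130:02d}")
        else:
            raise DataMatrixError(f"codeword {cw} not ASCII encodation")
        i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# standard ECC 200 placement


def _placement(nrow: int, ncol: int) -> list[list[tuple[int, int] | str | None]]:
    """Map each data-region module to (codeword index, bit index 0=MSB)."""
    array: list[list[tuple[int, int] | str | None]] = [
        [None] * ncol for _ in range(nrow)
    ]

    def module(r: int, c: int, idx: int, bit: int) -> None:
        if r < 0:
            r += nrow
            c += 4 - ((nrow + 4) % 8)
        if c < 0:
            c += ncol
            r += 4 - ((ncol + 4) % 8)
        array[r][c] = (idx, bit)

    def utah(r: int, c: int, idx: int) -> None:
        module(r - 2, c - 2, idx, 0)
        module(r - 2, c - 1, idx, 1)
        module(r - 1, c - 2, idx, 2)
        module(r - 1, c - 1, idx, 3)
        module(r - 1, c, idx, 4)
        module(r, c - 2, idx, 5)
        module(r, c - 1, idx, 6)
        module(r, c, idx, 7)

    def corner1(idx: int) -> None:
        for bit, (r, c) in enumerate(
            [(nrow - 1, 0), (nrow - 1, 1), (nrow - 1, 2), (0, ncol - 2),
             (0, ncol - 1), (1, ncol - 1), (2, ncol - 1), (3, ncol - 1)]
        ):
            module(r, c, idx, bit)

    def corner2(idx: int) -> None:
        for bit, (r, c) in enumerate(
            [(nrow - 3, 0), (nrow - 2, 0), (nrow - 1, 0), (0, ncol - 4),
             (0, ncol - 3), (0, ncol - 2), (0, ncol - 1), (1, ncol - 1)]
        ):
            module(r, c, idx, bit)

    def corner3(idx: int) -> None:
        for bit, (r, c) in enumerate(
            [(nrow - 3, 0), (nrow - 2, 0), (nrow - 1, 0), (0, ncol - 2),
             (0, ncol - 1), (1, ncol - 1), (2, ncol - 1), (3, ncol - 1)]
        ):
            module(r, c, idx, bit)

    def corner4(idx: int) -> None:
        for bit, (r, c) in enumerate(
            [(nrow - 1, 0), (nrow - 1, ncol - 1), (0, ncol - 3), (0, ncol - 2),
             (0, ncol - 1), (1, ncol - 3), (1, ncol - 2), (1, ncol - 1)]
        ):
            module(r, c, idx, bit)

    idx = 0
    row, col = 4, 0
    while row < nrow or col < ncol:
        if row == nrow and col == 0:
            corner1(idx)
            idx += 1
        if row == nrow - 2 and col == 0 and ncol % 4:
            corner2(idx)
            idx += 1
        if row == nrow - 2 and col == 0 and ncol % 8 == 4:
            corner3(idx)
            idx += 1
        if row == nrow + 4 and col == 2 and not ncol % 8:
            corner4(idx)
            idx += 1
        while row >= 0 and col < ncol:
            if row < nrow and col >= 0 and array[row][col] is None:
                utah(row, col, idx)
                idx += 1
            row -= 2
            col += 2
        row += 1
        col += 3
        while row < nrow and col >= 0:
            if row >= 0 and col < ncol and array[row][col] is None:
                utah(row, col, idx)
                idx += 1
            row += 2
            col -= 2
        row += 3
        col += 1
    # fixed pattern in the unused lower-right 2x2 corner of some sizes
    if array[nrow - 1][ncol - 1] is None:
        array[nrow - 1][ncol - 1] = "fixed1"
        array[nrow - 2][ncol - 2] = "fixed1"
        array[nrow - 1][ncol - 2] = "fixed0"
        array[nrow - 2][ncol - 1] = "fixed0"
    return array


def _pick_size(n_data: int) -> tuple[int, int, int]:
    for size, data_cw, ecc_cw in _SIZES:
        if n_data <= data_cw:
            return size, data_cw, ecc_cw
    raise DataMatrixError(
        f"{n_data} data codewords exceed the largest supported symbol (26x26)"
    )


def encode(text: str) -> list[list[int]]:
    """Smallest fitting square ECC 200 symbol as a 0/1 matrix (1 = dark)."""
    if not text:
        raise DataMatrixError("cannot encode an empty string")
    data = _ascii_encode(text)
    size, data_cw, ecc_cw = _pick_size(len(data))
    if len(data) < data_cw:
        data = data + [_PAD]
        while len(data) < data_cw:
            data.append(_pad_codeword(len(data) + 1))
    codewords = data + rs_encode(GF_DM, data, ecc_cw, fcr=1)
    region = size - 2
    placement = _placement(region, region)
    m = [[0] * size for _ in range(size)]
    # frame: solid left column + bottom row, alternating top row + right column
    for i in range(size):
        m[size - 1][i] = 1
        m[i][0] = 1
        m[0][i] = 1 if i % 2 == 0 else 0
        m[i][size - 1] = 1 if i % 2 == 1 else 0
    for r in range(region):
        for c in range(region):
            cell = placement[r][c]
            if cell == "fixed1":
                bit = 1
            elif cell == "fixed0":
                bit = 0
            elif cell is None:
                raise AssertionError(f"placement left module ({r},{c}) unassigned")
            else:
                idx, bitpos = cell
                bit = (codewords[idx] >> (7 - bitpos)) & 1
            m[1 + r][1 + c] = bit
    return m


def decode(matrix: list[list[int]]) -> str:
    """Inverse read path: frame check, inverse placement, RS check, de-encodation."""
    size = len(matrix)
    entry = next((s for s in _SIZES if s[0] == size), None)
    if entry is None or any(len(row) != size for row in matrix):
        raise DataMatrixError(f"not a supported square symbol (size {size})")
    _, data_cw, ecc_cw = entry
    for i in range(size):
        if matrix[size - 1][i] != 1 or matrix[i][0] != 1:
            raise DataMatrixError("solid finder edge (left/bottom) broken")
        if matrix[0][i] != (1 if i % 2 == 0 else 0):
            raise DataMatrixError("clock track (top) broken")
        if matrix[i][size - 1] != (1 if i % 2 == 1 else 0):
            raise DataMatrixError("clock track (right) broken")
    region = size - 2
    placement = _placement(region, region)
    total = data_cw + ecc_cw
    codewords = [0] * total
    for r in range(region):
        for c in range(region):
            cell = placement[r][c]
            bit = matrix[1 + r][1 + c] & 1
            if cell == "fixed1":
                if bit != 1:
                    raise DataMatrixError("fixed corner pattern broken")
            elif cell == "fixed0":
                if bit != 0:
                    raise DataMatrixError("fixed corner pattern broken")
            else:
                idx, bitpos = cell
                if idx >= total:
                    raise DataMatrixError("placement index out of range")
                if bit:
                    codewords[idx] |= 1 << (7 - bitpos)
    if any(rs_syndromes(GF_DM, codewords, ecc_cw, fcr=1)):
        raise DataMatrixError("Reed-Solomon syndromes non-zero: symbol is corrupted")
    return _ascii_decode(codewords[:data_cw])
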