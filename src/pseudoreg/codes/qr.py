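"""QR symbols (versions 1-3, error correction level M, byte mode).

Small-version QR is one of the three symbologies printed on biosample
labels; vial IDs are short, so versions beyond 3 (42 bytes at level M) are
never needed. The encoder builds the module matrix from scratch (function
patterns, format BCH, mask, zigzag codeword placement); the decoder walks
the inverse path — read and BCH-check the format info, unmask, collect
codewords, verify the Reed-Solomon syndromes, parse byte mode — and is the
independent read-back used in label round-trip tests.
"""

from __future__ import annotations

from .gf256 import GF_QR, rs_encode, rs_syndromes


class QRError(ValueError):
    pass


# version -> (data codewords, ecc codewords) at level M, single RS block
_VERSIONS = {1: (16, 10), 2: (28, 16), 3: (44, 26)}
_REMAINDER_BITS = {1: 0, 2: 7, 3: 7}
_ALIGNMENT_CENTER = {2: 18, 3: 22}

_FORMAT_G = 0b10100110111
_FORMAT_MASK = 0b101010000010010
_ECL_M = 0b00


def _bch_format(data5: int) -> int:
    rem = data5 << 10
    for shift in range(4, -1, -1):
        if rem & (1 << (10 + shift)):
            rem ^= _FORMAT_G << shift
    return ((data5 << 10) | rem) ^ _FORMAT_MASK


def _bch_check(bits15: int) -> bool:
    rem = bits15 ^ _FORMAT_MASK
    for shift in range(4, -1, -1):
        if rem & (1 << (10 + shift)):
            rem ^= _FORMAT_G << shift
    return (rem & 0x3FF) == 0


def _build_function_patterns(version: int) -> tuple[list[list[int]], list[list[bool]]]:
    size = 17 + 4 * version
    m = [[0] * size for _ in range(size)]
    func = [[False] * size for _ in range(size)]

    def set_func(r: int, c: int, v: int) -> None:
        m[r][c] = v
        func[r][c] = True

    def finder(r0: int, c0: int) -> None:
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if 0 <= r < size and 0 <= c < size:
                    inside = 0 <= dr <= 6 and 0 <= dc <= 6
                    ring = inside and (dr in (0, 6) or dc in (0, 6))
                    core = inside and 2 <= dr <= 4 and 2 <= dc <= 4
                    set_func(r, c, 1 if (ring or core) else 0)

    finder(0, 0)
    finder(0, size - 7)
    finder(size - 7, 0)
    for i in range(8, size - 8):  # timing
        set_func(6, i, (i + 1) % 2)
        set_func(i, 6, (i + 1) % 2)
    p = _ALIGNMENT_CENTER.get(version)
    if p is not None:
        for dr in range(-2, 3):
            for dc in range(-2, 3):
                ring = max(abs(dr), abs(dc))
                set_func(p + dr, p + dc, 1 if ring != 1 else 0)
    set_func(4 * version + 9, 8, 1)  # dark module
    for r, c in _format_positions(size):
        if not func[r][c]:
            set_func(r, c, 0)  # reserve format areas
    return m, func


def _format_positions(size: int) -> list[tuple[int, int]]:
    """Both 15-bit format-info copies, bit 0 first."""
    copy1 = (
        [(8, c) for c in range(6)]
        + [(8, 7), (8, 8), (7, 8)]
        + [(r, 8) for r in range(5, -1, -1)]
    )
    copy2 = [(size - 1 - i, 8) for i in range(7)] + [(8, size - 8 + i) for i in range(8)]
    return copy1 + copy2


def _data_coordinates(size: int, func: list[list[bool]]) -> list[tuple[int, int]]:
    coords = []
    col = size - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(size - 1, -1, -1) if upward else range(size)
        for r in rows:
            for c in (col, col - 1):
                if not func[r][c]:
                    coords.append((r, c))
        upward = not upward
        col -= 2
    return coords


def _mask0(r: int, c: int) -> int:
    return 1 if (r + c) % 2 == 0 else 0


def _codewords(text: str, version: int) -> list[int]:
    data_cw, ecc_cw = _VERSIONS[version]
    payload = text.encode("utf-8")
    bits = "0100" + format(len(payload), "08b") + "".join(format(b, "08b") for b in payload)
    if len(bits) > data_cw * 8:
        raise QRError(f"{len(payload)} bytes exceed version {version}-M capacity")
    bits += "0" * min(4, data_cw * 8 - len(bits))  # terminator
    bits += "0" * (-len(bits) % 8)
    data = [int(bits[i : i + 8], 2) for i in range(0, len(bits), 8)]
    pads = (0xEC, 0x11)
    while len(data) < data_cw:
        data.append(pads[(len(data) - (len(bits) // 8)) % 2])
    return data + rs_encode(GF_QR, data, ecc_cw, fcr=0)


def encode(text: str) -> list[list[int]]:
    """Smallest fitting version 1-3 symbol at level M, mask pattern 0."""
    payload_len = len(text.encode("utf-8"))
    version = next(
        (v for v, (d, _) in sorted(_VERSIONS.items()) if payload_len <= d - 2), None
    )
    if version is None:
        raise QRError(f"text of {payload_len} bytes does not fit a version-3 symbol")
    data_cw, ecc_cw = _VERSIONS[version]
    m, func = _build_function_patterns(version)
    size = len(m)
    coords = _data_coordinates(size, func)
    total_bits = 8 * (data_cw + ecc_cw) + _REMAINDER_BITS[version]
    if len(coords) != total_bits:
        raise AssertionError(
            f"function-pattern map inconsistent: {len(coords)} data modules, "
            f"expected {total_bits}"
        )
    bitstream = "".join(format(cw, "08b") for cw in _codewords(text, version))
    bitstream += "0" * _REMAINDER_BITS[version]
    for (r, c), b in zip(coords, bitstream):
        m[r][c] = int(b) ^ _mask0(r, c)
    fmt = _bch_format((_ECL_M << 3) | 0)  # mask id 0
    positions = _format_positions(size)
    for i in range(15):
        bit = (fmt >> i) & 1
        r, c = positions[i]
        m[r][c] = bit
        r, c = positions[15 + i]
        m[r][c] = bit
    m[4 * ((size - 17) // 4) + 9][8] = 1  # dark module stays dark
    return m


_MASKS = {
    0: lambda r, c: (r + c) % 2 == 0,
    1: lambda r, c: r % 2 == 0,
    2: lambda r, c: c % 3 == 0,
    3: lambda r, c: (r + c) % 3 == 0,
    4: lambda r, c: (r // 2 + c // 3) % 2 == 0,
    5: lambda r, c: (r * c) % 2 + (r * c) % 3 == 0,
    6: lambda r, c: ((r * c) % 2 + (r * c) % 3) % 2 == 0,
    7: lambda r, c: ((r + c) % 2 + (r * c) % 3) % 2 == 0,
}


def decode(matrix: list[list[int]]) -> str:
    """Independent read path: format BCH -> unmask -> codewords -> RS check -> text."""
    size = len(matrix)
    if size not in (21, 25, 29) or any(len(row) != size for row in matrix):
        raise QRError(f"not a version 1-3 matrix (size {size})")
    version = (size - 17) // 4
    data_cw, ecc_cw = _VERSIONS[version]
    _, func = _build_function_patterns(version)
    positions = _format_positions(size)
    fmt = 0
    for i in range(15):
        r, c = positions[i]
        fmt |= (matrix[r][c] & 1) << i
    if not _bch_check(fmt):
        raise QRError("format information fails its BCH check")
    data5 = (fmt ^ _FORMAT_MASK) >> 10
    ecl, mask_id = data5 >> 3, data5 & 0b111
    if ecl != _ECL_M:
        raise QRError(f"unsupported error-correction level bits {ecl:02b}")
    mask = _MASKS[mask_id]
    coords = _data_coordinates(size, func)
    bits = []
    for r, c in coords:
        bits.append((matrix[r][c] ^ (1 if mask(r, c) else 0)) & 1)
    total = data_cw + ecc_cw
    codewords = [
        int("".join(map(str, bits[i : i + 8])), 2) for i in range(0, total * 8, 8)
    ]
    if any(rs_syndromes(GF_QR, codewords, ecc_cw, fcr=0)):
        raise QRError("Reed-Solomon syndromes non-zero: symbol is corrupted")
    stream = "".join(format(cw, "08b") for cw in codewords[:data_cw])
    if stream[:4] != "0100":
        raise QRError(f"unsupported mode indicator {stream[:4]}")
    n = int(stream[4:12], 2)
    payload_bits = stream[12 : 12 + 8 * n]
    if len(payload_bits) < 8 * n:
        raise QRError("byte count exceeds available data")
    return bytes(
        int(payload_bits[i : i + 8], 2) for i in range(0, 8 * n, 8)
    ).decode("utf-8")
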