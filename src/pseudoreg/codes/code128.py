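"""Code 128 (code set B) linear barcode: encode to modules, decode from modules.

Each symbol is 11 modules expressed as 6 alternating bar/space widths; the
stop pattern is 13 modules. A modulo-103 check symbol is mandatory. The
encoder emits a module stream (1 = bar) with 10-module quiet zones; the
decoder walks the stream back through run lengths, reverses the width
table, and verifies the checksum — an independent read path used as the
round-trip oracle for printed labels.
"""

from __future__ import annotations

# width patterns for symbol values 0..106 (106 = stop, 13 modules)
_PATTERNS = [
    "212222", "222122", "222221", "121223", "121322", "131222", "122213",
    "122312", "132212", "221213", "221312", "231212", "112232", "122132",
    "122231", "113222", "123122", "123221", "223211", "221132", "221231",
    "213212", "223112", "312131", "311222", "321122", "321221", "312212",
    "322112", "322211", "212123", "212321", "232121", "111323", "131123",
    "131321", "112313", "132113", "132311", "211313", "231113", "231311",
    "112133", "112331", "132131", "113123", "113321", "133121", "313121",
    "211331", "231131", "213113", "213311", "213131", "311123", "311321",
    "331121", "312113", "312311", "332111", "314111", "221411", "431111",
    "111224", "111422", "121124", "121421", "141122", "141221", "112214",
    "112412", "122114", "122411", "142112", "142211", "241211", "221114",
    "413111", "241112", "134111", "111242", "121142", "121241", "114212",
    "124112", "124211", "411212", "421112", "421211", "212141", "214121",
    "412121", "111143", "111341", "131141", "114113", "114311", "411113",
    "411311", "113141", "114131", "311141", "411131", "211412", "211214",
    "211232", "2331112",
]
# structural self-check: every data symbol spans 11 modules, the stop 13
assert all(sum(int(d) for d in p) == 11 for p in _PATTERNS[:106])
assert sum(int(d) for d in _PATTERNS[106]) == 13

_START_B = 104
_STOP = 106
_QUIET = 10

_FROM_WIDTHS = {p: v for v, p in enumerate(_PATTERNS)}


class Code128Error(ValueError):
    pass


def _value_b(ch: str) -> int:
    o = ord(ch)
    if not (32 <= o <= 127):
        raise Code128Error(f"character {ch!r} not encodable in Code 128 set B")
    return o - 32


def encode(text: str) -> list[int]:
    """Module stream (1=bar, 0=space) incl. quiet zones for *text* in set B."""
    if not text:
        raise Code128Error("cannot encode an empty string")
    values = [_START_B] + [_value_b(c) for c in text]
    check = values[0] + sum(i * v for i, v in enumerate(values[1:], start=1))
    values.append(check % 103)
    values.append(_STOP)
    modules: list[int] = [0] * _QUIET
    for v in values:
        bar = 1
        for w in _PATTERNS[v]:
            modules.extend([bar] * int(w))
            bar ^= 1
    modules.extend([0] * _QUIET)
    return modules


def decode(modules: list[int]) -> str:
    """Read a module stream back to text; raises Code128Error on any defect."""
    # strip quiet zones
    try:
        start = modules.index(1)
    except ValueError:
        raise Code128Error("no bars found") from None
    end = len(modules) - modules[::-1].index(1)
    stream = modules[start:end]
    # run lengths, alternating bar/space starting with a bar
    widths: list[int] = []
    cur, run = stream[0], 1
    for m in stream[1:]:
        if m == cur:
            run += 1
        else:
            widths.append(run)
            cur, run = m, 1
    widths.append(run)
    if len(widths) < 6 + 7 or (len(widths) - 7) % 6 != 0:
        raise Code128Error(f"module stream has {len(widths)} runs; not a Code 128 symbol")
    symbols = [widths[i : i + 6] for i in range(0, len(widths) - 7, 6)]
    stop = widths[-7:]
    if "".join(map(str, stop)) != _PATTERNS[_STOP]:
        raise Code128Error("stop pattern mismatch")
    values = []
    for s in symbols:
        key = "".join(map(str, s))
        if key not in _FROM_WIDTHS:
            raise Code128Error(f"unknown symbol pattern {key}")
        values.append(_FROM_WIDTHS[key])
    if values[0] != _START_B:
        raise Code128Error(f"unsupported start symbol {values[0]}")
    *body, check = values
    expected = (body[0] + sum(i * v for i, v in enumerate(body[1:], start=1))) % 103
    if check != expected:
        raise Code128Error("checksum mismatch")
    out = []
    for v in body[1:]:
        if v > 94:
            raise Code128Error(f"control symbol {v} unsupported in this reader")
        out.append(chr(v + 32))
    return "".join(out)


def to_matrix(modules: list[int], height: int = 1) -> list[list[int]]:
    """A 1-D barcode as a (height x width) 0/1 matrix for uniform rendering."""
    return [list(modules) for _ in range(height)]
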