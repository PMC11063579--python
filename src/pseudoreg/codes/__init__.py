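"""Machine-readable symbologies for biosample labels.

Uniform surface over the three supported symbologies; every encoder
returns a 0/1 module matrix (1 = dark) and every decoder reads such a
matrix back to text, raising on any structural or checksum defect.
"""

from __future__ import annotations

from . import code128, datamatrix, qr

SYMBOLOGIES = ("datamatrix", "qr", "code128")


def encode_matrix(text: str, symbology: str) -> list[list[int]]:
    if symbology == "datamatrix":
        return datamatrix.encode(text)
    if symbology == "qr":
        return qr.encode(text)
    if symbology == "code128":
        return code128.to_matrix(code128.encode(text))
    raise ValueError(f"unknown symbology {symbology!r}; choose from {SYMBOLOGIES}")


def decode_matrix(matrix: list[list[int]], symbology: str) -> str:
    if symbology == "datamatrix":
        return datamatrix.decode(matrix)
    if symbology == "qr":
        return qr.decode(matrix)
    if symbology == "code128":
        return code128.decode(list(matrix[0]))
    raise ValueError(f"unknown symbology {symbology!r}; choose from {SYMBOLOGIES}")
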