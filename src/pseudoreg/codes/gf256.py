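"""GF(256) arithmetic and Reed–Solomon coding shared by the 2-D symbologies.

QR and DataMatrix both protect their codewords with Reed–Solomon codes over
GF(2^8) but differ in the field's primitive polynomial (0x11D vs 0x12D) and
the first consecutive root of the generator (0 vs 1), so everything here is
parameterized by both.
"""

from __future__ import annotations


class GF256:
    def __init__(self, primitive_poly: int):
        self.exp = [0] * 512
        self.log = [0] * 256
        x = 1
        for i in range(255):
            self.exp[i] = x
            self.log[x] = i
            x <<= 1
            if x & 0x100:
                x ^= primitive_poly
        for i in range(255, 512):
            self.exp[i] = self.exp[i - 255]

    def mul(self, a: int, b: int) -> int:
        if a == 0 or b == 0:
            return 0
        return self.exp[self.log[a] + self.log[b]]

    def poly_mul(self, p: list[int], q: list[int]) -> list[int]:
        out = [0] * (len(p) + len(q) - 1)
        for i, a in enumerate(p):
            if a:
                for j, b in enumerate(q):
                    out[i + j] ^= self.mul(a, b)
        return out

    def poly_eval(self, poly: list[int], x: int) -> int:
        # Horner, highest-order coefficient first
        y = 0
        for c in poly:
            y = self.mul(y, x) ^ c
        return y


def generator_poly(gf: GF256, nsym: int, fcr: int) -> list[int]:
    """(x - a^fcr)(x - a^(fcr+1)) ... , highest order first."""
    g = [1]
    for i in range(nsym):
        g = gf.poly_mul(g, [1, gf.exp[fcr + i]])
    return g


def rs_encode(gf: GF256, data: list[int], nsym: int, fcr: int) -> list[int]:
    """Parity codewords: remainder of data * x^nsym mod generator."""
    gen = generator_poly(gf, nsym, fcr)
    rem = list(data) + [0] * nsym
    for i in range(len(data)):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= gf.mul(gen[j], coef)
    return rem[len(data):]


def rs_syndromes(gf: GF256, codeword: list[int], nsym: int, fcr: int) -> list[int]:
    """All-zero iff the codeword (data + parity, highest order first) is valid."""
    return [gf.poly_eval(codeword, gf.exp[fcr + i]) for i in range(nsym)]


GF_QR = GF256(0x11D)
GF_DM = GF256(0x12D)
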