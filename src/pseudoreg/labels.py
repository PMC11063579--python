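"""Printable biosample labels.

Each label shows the biosample ID, the owning subject ID, the visit and
sample-type display labels, plus a machine-readable symbol (DataMatrix by
default, QR or Code 128 selectable) whose content is *exactly* the
biosample ID — scanners in the lab track vials by that ID alone.

Output is one self-contained HTML document (inline CSS, inline SVG, zero
external references): labels are printed from a browser on the device
that holds the data, and nothing may require network access.
"""

from __future__ import annotations

import html as _html
import math
from dataclasses import dataclass

from .codes import SYMBOLOGIES, encode_matrix
from .config import StudyConfig
from .errors import PseudoregError
from .registry import BiosampleRecord


class LabelError(PseudoregError):
    pass


@dataclass(frozen=True)
class LabelPayload:
    biosample_id: str
    subject_id: str
    visit_label: str
    sample_type_label: str


@dataclass(frozen=True)
class SheetLayout:
    rows: int = 4
    columns: int = 3
    repeat_count: int = 1

    def __post_init__(self):
        if self.rows < 1 or self.columns < 1 or self.repeat_count < 1:
            raise ValueError("rows, columns and repeat_count must be >= 1")


def build_label_payload(sample: BiosampleRecord, config: StudyConfig) -> LabelPayload:
    """Resolve a biosample record's visit/type codes to display labels."""
    visit = config.visit_map().get(sample.visit_id)
    if visit is None:
        raise LabelError(f"visit {sample.visit_id!r} not in the study schedule")
    stype = config.sample_type_map().get(sample.sample_type)
    if stype is None:
        raise LabelError(f"sample type {sample.sample_type!r} not configured")
    return LabelPayload(
        biosample_id=sample.pseudonym,
        subject_id=sample.subject_pseudonym,
        visit_label=visit.label,
        sample_type_label=stype.label,
    )


def encode_code(payload: LabelPayload, symbology: str = "datamatrix") -> list[list[int]]:
    """Module matrix for the payload's biosample ID in the chosen symbology."""
    if not payload.biosample_id:
        raise LabelError("biosample_id must be non-empty")
    if symbology not in SYMBOLOGIES:
        raise LabelError(f"unknown symbology {symbology!r}; choose from {SYMBOLOGIES}")
    return encode_matrix(payload.biosample_id, symbology)


def layout_sheet(
    payloads: list[LabelPayload], layout: SheetLayout
) -> list[list[LabelPayload | None]]:
    """Place payloads row-major onto fixed-size pages.

    ``repeat_count`` duplicates each payload into adjacent cells; blanks
    (None) trail on the final page. Input order is preserved.
    """
    if not payloads:
        raise LabelError("payload list must be non-empty")
    cells: list[LabelPayload | None] = []
    for p in payloads:
        cells.extend([p] * layout.repeat_count)
    per_page = layout.rows * layout.columns
    n_pages = math.ceil(len(cells) / per_page)
    cells.extend([None] * (n_pages * per_page - len(cells)))
    return [cells[i * per_page : (i + 1) * per_page] for i in range(n_pages)]


def _matrix_svg(matrix: list[list[int]], module_px: int = 3) -> str:
    h = len(matrix)
    w = len(matrix[0])
    quiet = 2
    rects = []
    for r, row in enumerate(matrix):
        c = 0
        while c < len(row):  # merge horizontal runs to keep the SVG small
            if row[c]:
                start = c
                while c < len(row) and row[c]:
                    c += 1
                rects.append(
                    f'<rect x="{(quiet + start) * module_px}" y="{(quiet + r) * module_px}" '
                    f'width="{(c - start) * module_px}" height="{module_px}"/>'
                )
            else:
                c += 1
    width = (w + 2 * quiet) * module_px
    height = (h + 2 * quiet) * module_px
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {width} {height}" '
        f'width="{width}" height="{height}" shape-rendering="crispEdges">'
        f'<rect width="{width}" height="{height}" fill="#fff"/>'
        f'<g fill="#000">{"".join(rects)}</g></svg>'
    )


_CSS = """
body { font-family: sans-serif; margin: 0; }
.page { display: grid; gap: 2mm; padding: 6mm; page-break-after: always; }
.cell { border: 0.2mm dashed #999; padding: 1.5mm; min-height: 22mm;
        display: flex; gap: 2mm; align-items: center; }
.cell.blank { border-style: none; }
.ids { font-size: 8pt; line-height: 1.35; }
.ids .bid { font-weight: bold; font-family: monospace; }
.ids .sid { font-family: monospace; }
.meta { color: #333; }
@media print { .cell { border-color: #eee; } }
"""


def render_sheet_html(
    pages: list[list[LabelPayload | None]],
    config: StudyConfig,
    symbology: str = "datamatrix",
    columns: int | None = None,
    title: str = "Biosample labels",
) -> str:
    """One self-contained printable document; all assets inlined, no fetches.

    ``columns`` is the grid width of the layout that produced the pages;
    when omitted, the squarest divisor of the page size is used.
    """
    if symbology not in SYMBOLOGIES:
        raise LabelError(f"unknown symbology {symbology!r}; choose from {SYMBOLOGIES}")
    svg_cache: dict[str, str] = {}
    out = [
        "<!DOCTYPE html>",
        '<html lang="en"><head><meta charset="utf-8">',
        f"<title>{_html.escape(title)}</title>",
        f"<style>{_CSS}</style></head><body>",
    ]
    for page in pages:
        cols = columns or _default_columns(len(page))
        out.append(f'<div class="page" style="grid-template-columns: repeat({cols}, 1fr);">')
        for cell in page:
            if cell is None:
                out.append('<div class="cell blank"></div>')
                continue
            svg = svg_cache.get(cell.biosample_id)
            if svg is None:
                svg = _matrix_svg(encode_matrix(cell.biosample_id, symbology))
                svg_cache[cell.biosample_id] = svg
            out.append(
                '<div class="cell">'
                + svg
                + '<div class="ids">'
                + f'<div class="bid">{_html.escape(cell.biosample_id)}</div>'
                + f'<div class="sid">{_html.escape(cell.subject_id)}</div>'
                + f'<div class="meta">{_html.escape(cell.visit_label)} &middot; '
                + f"{_html.escape(cell.sample_type_label)}</div>"
                + "</div></div>"
            )
        out.append("</div>")
    out.append("</body></html>")
    return "\n".join(out)


def _default_columns(n: int) -> int:
    root = max(1, round(math.sqrt(n)))
    for c in range(root, 0, -1):
        if n % c == 0:
            return c
    return 1


def render_labels(
    payloads: list[LabelPayload],
    layout: SheetLayout,
    config: StudyConfig,
    symbology: str = "datamatrix",
    title: str = "Biosample labels",
) -> str:
    """layout + render in one step, with the true column count."""
    pages = layout_sheet(payloads, layout)
    return render_sheet_html(
        pages, config, symbology=symbology, columns=layout.columns, title=title
    )


@dataclass(frozen=True)
class BulkParseError:
    line_no: int
    message: str


def parse_bulk_input(text: str) -> tuple[list[LabelPayload], list[BulkParseError]]:
    """Parse pasted bulk-label lines: ``biosample_id TAB/;/, subject_id, visit, type``.

    Row-level errors are collected with their line numbers, never fail-fast;
    well-formed lines are kept in order. Empty input parses to an empty list.
    """
    payloads: list[LabelPayload] = []
    errors: list[BulkParseError] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if "\t" in line:
            parts = [p.strip() for p in line.split("\t")]
        elif ";" in line:
            parts = [p.strip() for p in line.split(";")]
        else:
            parts = [p.strip() for p in line.split(",")]
        if len(parts) != 4:
            errors.append(
                BulkParseError(line_no, f"expected 4 fields, got {len(parts)}")
            )
            continue
        if not parts[0]:
            errors.append(BulkParseError(line_no, "biosample_id is empty"))
            continue
        payloads.append(
            LabelPayload(
                biosample_id=parts[0],
                subject_id=parts[1],
                visit_label=parts[2],
                sample_type_label=parts[3],
            )
        )
    return payloads, errors
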