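"""Document ingestion: convert TXT/HTML/DOCX article files to normalized raw text.

The checker operates on plain character streams.  Whatever the source format,
the text handed to the extractor has been through :func:`normalize_text`,
which canonicalizes the Unicode look-alikes that word processors and
typesetting pipelines introduce (typographic minus signs, non-breaking
spaces, ligatures, superscript digits) so that one grammar can match them
all.  Normalization is idempotent.
"""

from __future__ import annotations

import re
import unicodedata
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import lxml.etree
import lxml.html

__all__ = ["RawDocument", "IngestError", "load_document", "normalize_text"]


class IngestError(Exception):
    """A document could not be read or its format is unsupported."""


@dataclass(frozen=True)
class RawDocument:
    """Normalized text of one article plus identifying metadata.

    Parameters
    ----------
    doc_id:
        Opaque identifier, by default the filename stem.
    text:
        Normalized character string; contains no markup after HTML/DOCX
        conversion.
    source_format:
        One of ``{"txt", "html", "docx", "pdf"}``.
    year:
        Optional publication year used only for per-year prevalence trends.
    """

    doc_id: str
    text: str
    source_format: str = "txt"
    year: Optional[int] = None


# Character-level canonicalization table.  Hyphen/minus variants collapse to
# ASCII hyphen because a leading minus on a statistic must survive extraction;
# exotic spaces collapse to ASCII space so the grammar's optional-space rules
# apply uniformly.
_CHAR_MAP = {
    "−": "-",  # minus sign
    "‐": "-",  # hyphen
    "‑": "-",  # non-breaking hyphen
    "‒": "-",  # figure dash
    "–": "-",  # en dash (frequently used as minus in PDFs)
    "—": "-",  # em dash
    " ": " ",  # no-break space
    " ": " ",  # thin space
    " ": " ",  # hair space
    " ": " ",  # en space
    " ": " ",  # em space
    " ": " ",  # narrow no-break space
    "­": "",   # soft hyphen
    "​": "",   # zero-width space
    "﻿": "",   # BOM / zero-width no-break space
}
_TRANSLATION = str.maketrans(_CHAR_MAP)

# Collapse runs of blanks within a line but keep line structure: a result
# never spans a paragraph break, and offsets stay meaningful.
_BLANK_RUN = re.compile(r"[ \t\f\v]+")


def normalize_text(raw: str) -> str:
    """Canonicalize characters so the extraction grammar sees one alphabet.

    NFKC expands ligatures and folds superscript digits (so the chi-square
    glyph ``χ²`` becomes ``χ2``); the translation table maps minus/dash and
    space variants to ASCII; emphasis asterisks (``*t*(28)``) are dropped;
    blank runs collapse to single spaces while newlines are retained.
    Total and idempotent.
    """
    s = unicodedata.normalize("NFKC", raw)
    s = s.translate(_TRANSLATION)
    s = s.replace("*", "")
    s = _BLANK_RUN.sub(" ", s)
    return s


def _read_txt(path: Path) -> str:
    return path.read_text(encoding="utf-8", errors="replace")


def _read_html(path: Path) -> str:
    try:
        tree = lxml.html.parse(str(path))
    except Exception as exc:  # lxml raises a zoo of parse errors
        raise IngestError(f"cannot parse HTML file {path}: {exc}") from exc
    root = tree.getroot()
    if root is None:
        return ""
    for bad in root.iter("script", "style"):
        bad.drop_tree()
    return root.text_content()


_W_NS = "http://schemas.openxmlformats.org/wordprocessingml/2006/main"


def _read_docx(path: Path) -> str:
    """Extract paragraph text from WordprocessingML (a zip of XML parts)."""
    try:
        with zipfile.ZipFile(path) as zf:
            xml = zf.read("word/document.xml")
    except (zipfile.BadZipFile, KeyError, OSError) as exc:
        raise IngestError(f"cannot read DOCX file {path}: {exc}") from exc
    root = lxml.etree.fromstring(xml)
    paragraphs = []
    for para in root.iter(f"{{{_W_NS}}}p"):
        runs = [t.text or "" for t in para.iter(f"{{{_W_NS}}}t")]
        paragraphs.append("".join(runs))
    return "\n".join(paragraphs)


_READERS = {"txt": _read_txt, "html": _read_html, "docx": _read_docx}
_EXT_TO_FORMAT = {
    ".txt": "txt",
    ".text": "txt",
    ".html": "html",
    ".htm": "html",
    ".xhtml": "html",
    ".docx": "docx",
    ".pdf": "pdf",
}


def load_document(
    path: str | Path,
    format_hint: Optional[str] = None,
    year: Optional[int] = None,
) -> RawDocument:
    """Read an article file and return its normalized text.

    The format is taken from ``format_hint`` when given, otherwise inferred
    from the file extension.  Empty documents yield empty text, not an error.

    Raises
    ------
    IngestError
        For unreadable or corrupt files, for an unsupported extension without
        a hint, and for PDF input (no PDF text extractor is bundled; convert
        PDFs to text or HTML upstream).
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    fmt = (format_hint or _EXT_TO_FORMAT.get(path.suffix.lower(), "")).lower()
    if not fmt:
        raise IngestError(
            f"cannot infer format of {path} from its extension; pass format_hint"
        )
    if fmt == "pdf":
        raise IngestError(
            f"{path}: PDF text extraction is not supported; "
            "convert the article to text, HTML, or DOCX first"
        )
    try:
        reader = _READERS[fmt]
    except KeyError:
        raise IngestError(f"unsupported format {fmt!r} for {path}") from None
    text = normalize_text(reader(path))
    return RawDocument(doc_id=path.stem, text=text, source_format=fmt, year=year)
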