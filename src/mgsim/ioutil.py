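"""Small I/O helpers shared across modules."""

from __future__ import annotations

import gzip
import io
from pathlib import Path


def open_text(path, mode: str = "wt"):
    """Open plain or gzip text by extension.

    Gzip members are written with mtime=0 so reruns with the same seed
    produce byte-identical compressed files.
    """
    path = str(path)
    if path.endswith(".gz"):
        raw = gzip.GzipFile(path, mode.replace("t", "") + "b" if "b" not in mode else mode, mtime=0)
        if "r" in mode:
            return io.TextIOWrapper(raw)
        return io.TextIOWrapper(raw, write_through=True)
    return open(path, mode)


def gzip_file(path, remove_original: bool = True) -> Path:
    """Compress a file to ``path + '.gz'`` deterministically (mtime=0)."""
    path = Path(path)
    out = Path(str(path) + ".gz")
    with open(path, "rb") as src, gzip.GzipFile(str(out), "wb", mtime=0) as dst:
        while chunk := src.read(1 << 20):
            dst.write(chunk)
    if remove_original:
        path.unlink()
    return out
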