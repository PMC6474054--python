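"""Small shared helpers: atomic file writes, gzip-aware opening, digests."""

from __future__ import annotations

import gzip
import hashlib
import io
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path


def open_maybe_gzip(path, mode: str = "rt"):
    """Open ``path`` with gzip if its name ends in .gz, else plainly."""
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@contextmanager
def atomic_write(path, mode: str = "wt"):
    """Write to a temp file in the target directory, rename on success.

    Guarantees that readers never observe a half-written file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        if path.name.endswith(".gz"):
            handle = gzip.open(tmp, mode)
        else:
            handle = open(tmp, mode)
        with handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def file_md5(path, chunk: int = 1 << 20) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        while True:
            block = fh.read(chunk)
            if not block:
                break
            h.update(block)
    return h.hexdigest()


def as_line_stream(source):
    """Accept a path, a string of file content, or a file-like; yield lines.

    A string containing a newline or a tab is treated as literal content,
    anything else as a path.
    """
    if hasattr(source, "read"):
        return iter(source)
    if isinstance(source, (str, bytes)):
        text = source.decode() if isinstance(source, bytes) else source
        if "\n" in text or "\t" in text:
            return iter(io.StringIO(text))
        return open_maybe_gzip(text, "rt")
    return open_maybe_gzip(os.fspath(source), "rt")
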