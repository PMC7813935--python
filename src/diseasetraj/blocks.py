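"""ICD-10 disease blocks: mapping 3-character codes to block indices.

The analysis universe is the somatic range A00-N99 (ICD-10 chapters I-XIV),
grouped into contiguous WHO disease blocks. The default table shipped with the
package has M = 131 blocks; any edited table with sorted, non-overlapping
ranges can be substituted and every downstream algorithm follows its M.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}$")

CodeKey = tuple[str, int]


def code_key(code: str) -> CodeKey:
    """Validate a 3-character ICD-10 code and return its sortable key.

    Raises ValueError on anything that is not letter + two digits.
    """
    if not isinstance(code, str) or not _CODE_RE.match(code):
        raise ValueError(f"malformed ICD-10 code {code!r} (expected e.g. 'E11')")
    return (code[0], int(code[1:]))


def parse_code_range(text: str) -> tuple[CodeKey, CodeKey]:
    """Parse 'E10-E14' (or a single code 'B99') into an inclusive key range."""
    parts = text.split("-")
    if len(parts) == 1:
        k = code_key(parts[0])
        return (k, k)
    if len(parts) != 2:
        raise ValueError(f"malformed code range {text!r}")
    lo, hi = code_key(parts[0]), code_key(parts[1])
    if hi < lo:
        raise ValueError(f"inverted code range {text!r}")
    return (lo, hi)


def code_in_range(code: str, rng: tuple[CodeKey, CodeKey]) -> bool:
    return rng[0] <= code_key(code) <= rng[1]


@dataclass(frozen=True)
class Block:
    index: int
    label: str
    start: str
    end: str

    @property
    def start_key(self) -> CodeKey:
        return code_key(self.start)

    @property
    def end_key(self) -> CodeKey:
        return code_key(self.end)


class BlockTable:
    """Ordered, non-overlapping ICD-10 block ranges covering the code universe.

    ICD-10 leaves some codes unassigned (e.g. A10-A14); those fall in gaps
    between blocks and map to ``None`` just like codes outside the universe.
    """

    def __init__(self, blocks: list[Block]):
        if not blocks:
            raise ValueError("block table is empty")
        self.blocks = list(blocks)
        for i, b in enumerate(self.blocks):
            if b.index != i:
                raise ValueError(f"block indices must be 0..M-1; got {b.index} at {i}")
            if b.end_key < b.start_key:
                raise ValueError(f"inverted range in block {b.label!r}")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start_key <= a.end_key:
                raise ValueError(
                    f"blocks {a.label!r} and {b.label!r} overlap or are unsorted"
                )
        self._starts = [b.start_key for b in self.blocks]
        self._by_start = {b.start: b.index for b in self.blocks}

    @property
    def M(self) -> int:
        return len(self.blocks)

    @property
    def universe(self) -> tuple[CodeKey, CodeKey]:
        return (self.blocks[0].start_key, self.blocks[-1].end_key)

    def map_code(self, code: str) -> int | None:
        """Block index whose range contains ``code``, or None if unassigned."""
        key = code_key(code)
        i = bisect.bisect_right(self._starts, key) - 1
        if i < 0:
            return None
        b = self.blocks[i]
        return b.index if key <= b.end_key else None

    def index_for_start(self, start_code: str) -> int:
        """Index of the block whose range begins at ``start_code``."""
        try:
            return self._by_start[start_code]
        except KeyError:
            raise ValueError(f"no block starts at {start_code!r}") from None

    def label(self, index: int) -> str:
        return self.blocks[index].label

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BlockTable":
        blocks = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["index", "label", "range_start", "range_end"]:
                raise ValueError(f"unexpected block table header in {path}")
            for line in fh:
                if not line.strip():
                    continue
                idx, label, start, end = line.rstrip("\n").split("\t")
                blocks.append(Block(int(idx), label, start, end))
        return cls(blocks)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("index\tlabel\trange_start\trange_end\n")
            for b in self.blocks:
                fh.write(f"{b.index}\t{b.label}\t{b.start}\t{b.end}\n")


def load_default_blocks() -> BlockTable:
    """The packaged 131-block WHO grouping of A00-N99."""
    ref = resources.files("diseasetraj.data") / "icd10_blocks_a00_n99.tsv"
    with resources.as_file(ref) as path:
        return BlockTable.from_tsv(path)


def map_code_to_block(code: str, table: BlockTable) -> int | None:
    """Functional alias for :meth:`BlockTable.map_code`."""
    return table.map_code(code)
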