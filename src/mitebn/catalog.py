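"""Canonical catalog of the eleven house dust mite allergen components.

The multiplex panel analysed by this package reports allergen-specific IgE
(sIgE, kU/L) for eleven Dermatophagoides molecules: the group 1 cysteine
proteases (Der f 1, Der p 1), the group 2 NPC2 proteins (Der f 2, Der p 2),
the group 5/21 pair, Der p 7, the tropomyosin Der p 10, the paramyosin
Der p 11, the arginine kinase Der p 20 and the peritrophin Der p 23.
All tabular I/O and all network code use this fixed canonical order.
"""

from __future__ import annotations

import re

#: Canonical component order: species, then numeric component index.
COMPONENTS: tuple[str, ...] = (
    "Der f 1",
    "Der f 2",
    "Der p 1",
    "Der p 2",
    "Der p 5",
    "Der p 7",
    "Der p 10",
    "Der p 11",
    "Der p 20",
    "Der p 21",
    "Der p 23",
)

_CANONICAL = {c.casefold(): c for c in COMPONENTS}


def normalize_header(raw: object) -> str:
    """Collapse whitespace/underscores and case-fold a column header."""
    return re.sub(r"[\s_]+", " ", str(raw)).strip().casefold()


def canonical_component(raw: object) -> str | None:
    """Map a header spelling to its canonical component name, if any.

    ``"Der_f_1"``, ``"der f 1"`` and ``" Der  f 1 "`` all map to
    ``"Der f 1"``; unknown names return ``None``.
    """
    return _CANONICAL.get(normalize_header(raw))
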