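"""The 16 MeSH top-level categories.

MeSH headings are organized into 16 lettered categories (Anatomy,
Organisms, Diseases, ...). Every term in a store carries exactly one of
these single-capital-letter codes.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Fixed code -> label mapping for the 16 MeSH categories.
CATEGORY_LABELS: dict[str, str] = {
    "A": "Anatomy",
    "B": "Organisms",
    "C": "Diseases",
    "D": "Chemicals and Drugs",
    "E": "Analytical, Diagnostic and Therapeutic Techniques and Equipment",
    "F": "Psychiatry and Psychology",
    "G": "Phenomena and Processes",
    "H": "Disciplines and Occupations",
    "I": "Anthropology, Education, Sociology and Social Phenomena",
    "J": "Technology and Food and Beverages",
    "K": "Humanities",
    "L": "Information Science",
    "M": "Persons",
    "N": "Health Care",
    "V": "Publication Type",
    "Z": "Geographical Locations",
}

VALID_CATEGORY_CODES: frozenset[str] = frozenset(CATEGORY_LABELS)


@dataclass(frozen=True)
class MeshCategory:
    """One of the 16 MeSH categories, identified by its letter code."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in CATEGORY_LABELS:
            raise ValueError(
                f"invalid MeSH category code {self.code!r}; "
                f"valid codes are {''.join(sorted(CATEGORY_LABELS))}"
            )

    @property
    def label(self) -> str:
        return CATEGORY_LABELS[self.code]
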