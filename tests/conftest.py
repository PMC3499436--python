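import json

import pytest

from peerfind.records_io import CitationCorpus, parse_medline


def make_corpus(records):
    """Build a corpus from (pmid, authors, year, journal, abstract) tuples
    or dicts, via the JSONL dialect so parsing is exercised too."""
    lines = []
    for rec in records:
        if isinstance(rec, dict):
            obj = {"title": "", "abstract": "", "journal_id": "J01", "year": 2005, **rec}
        else:
            pmid, authors = rec[0], rec[1]
            obj = {
                "pmid": pmid,
                "title": "",
                "abstract": rec[4] if len(rec) > 4 else "",
                "authors": list(authors),
                "journal_id": rec[3] if len(rec) > 3 else "J01",
                "year": rec[2] if len(rec) > 2 else 2005,
            }
        lines.append(json.dumps(obj))
    return parse_medline(lines, dialect="jsonl")


@pytest.fixture
def corpus_factory():
    return make_corpus


MEDLINE_TWO_RECORDS = """\
PMID- 101
TI  - Regulation of the cell cycle by cyclin-dependent kinases.
AB  - Cyclin-dependent kinases drive cell cycle transitions. Their
      activity is regulated by cyclins and inhibitors.
AU  - Smith JA
AU  - Lee K
JT  - Journal of Cell Biology
DP  - 2004 Mar 15

PMID- 102
TI  - Protein phosphatases in mitosis.
AB  - Phosphatases reverse kinase signalling during mitosis.
AU  - Smith JA
AU  - Wu Q
JT  - Molecular Cell
DP  - 2006 Jun
"""


@pytest.fixture
def medline_two_records():
    return MEDLINE_TWO_RECORDS
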