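import pytest

from lbdkit import AbstractRecord, Corpus


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Six hand-built documents exercising case, boundaries and phrases."""
    return Corpus(
        [
            AbstractRecord(
                "pm1",
                "EGFR mutations in breast cancer",
                "We studied EGFR and erlotinib response in tumors.",
                2010,
            ),
            AbstractRecord(
                "pm2",
                "Cancer of the breast",
                "The AHR-dependent pathway differs from SAHRA regulation.",
                2015,
            ),
            AbstractRecord(
                "pm3",
                "HER2 signalling",
                "HER2 and breast cancer co-expression with EGFR was noted.",
                2020,
            ),
            AbstractRecord(
                "pm4",
                "Unrelated botany",
                "Chlorophyll content in maize leaves under drought.",
                2005,
            ),
            AbstractRecord(
                "pm5",
                "Erlotinib pharmacokinetics",
                "erlotinib clearance was measured; egfr status unknown.",
                2018,
            ),
            AbstractRecord("pm6", "", "", None),
        ]
    )
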