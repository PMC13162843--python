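import numpy as np
import pytest

import clonotrack as ct


@pytest.fixture
def make_sample():
    """Factory: counts dict -> raw all-productive RepertoireSample."""

    def _make(counts, sample_id="s", subject_id="P1", compartment=ct.BLOOD, day=0):
        return ct.RepertoireSample.from_counts(
            list(counts), list(counts.values()), sample_id, subject_id, compartment, day
        )

    return _make


@pytest.fixture
def make_ready(make_sample):
    """Factory: counts dict -> productive-filtered sample with frequencies."""

    def _make(counts, **kw):
        return ct.compute_frequencies(make_sample(counts, **kw))

    return _make


@pytest.fixture
def mixed_status_sample():
    return ct.RepertoireSample.from_records(
        [
            ct.ClonotypeRecord("AAACCC", "CASSL", "V05", "J02", "productive", 5),
            ct.ClonotypeRecord("GGGTTT", "", "V07", "J01", "stop", 3),
            ct.ClonotypeRecord("TTTAAA", "", "V12", "J02", "frameshift", 2),
        ],
        sample_id="mixed",
        subject_id="P1",
    )


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


IMMUNOSEQ_HEADER = [
    "rearrangement",
    "aminoAcid",
    "count (templates/estimate)",
    "sequenceStatus",
    "vGeneName",
    "jGeneName",
]
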