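import numpy as np
import pytest

from ribolens import (
    LengthRange,
    ReadRecord,
    Reference,
    TranscriptRecord,
    build_experiment,
    write_store,
)


@pytest.fixture
def tiny_ref():
    """Two transcripts with the CDS coordinates used throughout the examples:
    T1 120 nt, CDS [30, 90); T2 80 nt, CDS [12, 48)."""
    return Reference(
        name="tiny",
        records=(
            TranscriptRecord("T1", 120, 30, 90),
            TranscriptRecord("T2", 80, 12, 48),
        ),
    )


@pytest.fixture
def tiny_annotation(tmp_path):
    p = tmp_path / "annotation.tsv"
    p.write_text("# id\tlength\tcds_start\tcds_end\nT1\t120\t30\t90\nT2\t80\t12\t48\n")
    return p


@pytest.fixture
def tiny_experiment(tiny_ref):
    """Four reads: lengths 28,28,28,30; one UTR5, two CDS, one UTR3 (by 5' end)."""
    reads = [
        ReadRecord(0, 18, 28),  # T1 UTR5, metagene_start p=-12
        ReadRecord(0, 30, 28),  # T1 CDS start codon, p=0
        ReadRecord(0, 86, 28),  # T1 CDS near stop, metagene_stop p=-1
        ReadRecord(1, 48, 30 - 18),  # length 12 < range -> not used here
    ]
    reads[3] = ReadRecord(1, 48, 30)  # T2 UTR3 (48 >= cds_end 48), length 30
    return build_experiment(reads, tiny_ref, LengthRange(15, 40), radius=50)


@pytest.fixture
def tiny_store(tmp_path, tiny_ref, tiny_experiment):
    path = tmp_path / "tiny.h5"
    write_store(path, tiny_ref, {"WT": tiny_experiment})
    return path
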