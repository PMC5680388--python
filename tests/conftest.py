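import numpy as np
import pytest

from sweepherd.popmap import PopulationMap
from sweepherd.vcfio import VariantTable


def make_table(records, samples, sample_dp=None):
    """Build a VariantTable from per-record dicts.

    Each record: chrom, pos, ref, alt, genotypes (list of dosages, -1
    missing) and optional qual/qd/fs/rprs/dp (default clean passing values).
    """
    n = len(records)
    cols = {
        "chrom": [], "pos": [], "ref": [], "alt": [],
        "qual": [], "qd": [], "fs": [], "rprs": [], "dp": [], "gt": [],
    }
    for r in records:
        cols["chrom"].append(r.get("chrom", "chr1"))
        cols["pos"].append(r["pos"])
        cols["ref"].append(r.get("ref", "A"))
        cols["alt"].append(r.get("alt", "G"))
        cols["qual"].append(r.get("qual", 2000.0))
        cols["qd"].append(r.get("qd", 25.0))
        cols["fs"].append(r.get("fs", 1.0))
        cols["rprs"].append(r.get("rprs", 0.0))
        cols["dp"].append(r.get("dp", 500.0))
        cols["gt"].append(r["genotypes"])
    return VariantTable(
        np.array(cols["chrom"], dtype=object), np.array(cols["pos"], dtype=np.int64),
        np.array(cols["ref"], dtype=object), np.array(cols["alt"], dtype=object),
        np.array(cols["qual"]), np.array(cols["qd"]), np.array(cols["fs"]),
        np.array(cols["rprs"]), np.array(cols["dp"]),
        np.array(cols["gt"], dtype=np.int8).reshape(n, len(samples)),
        list(samples), sample_dp=sample_dp,
    )


@pytest.fixture
def two_pop_map():
    return PopulationMap({"a1": "popA", "a2": "popA", "b1": "popB", "b2": "popB"})
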