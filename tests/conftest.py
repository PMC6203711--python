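import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nashsom import simulate
from nashsom.io import PairedSite, SitePileup

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def build_pileup(sample: str, chrom: str, pos: int, ref: str, reads) -> SitePileup:
    """Construct a SitePileup from a list of per-read dicts.

    Each read dict may set ``base`` (default ref), ``qual`` (35),
    ``repeat`` (False), ``off`` (50; distance from the 5' end of a
    100-base read).
    """
    bases, quals, mapqs, reps, d5s, d3s, strands = [], [], [], [], [], [], []
    for r in reads:
        bases.append(r.get("base", ref))
        quals.append(r.get("qual", 35))
        mapqs.append(r.get("mapq", 60))
        reps.append(bool(r.get("repeat", False)))
        off = r.get("off", 50)
        d5s.append(off)
        d3s.append(99 - off)
        strands.append(r.get("strand", "+"))
    return SitePileup(sample=sample, chrom=chrom, pos=pos, ref=ref,
                      bases=np.array(bases, dtype="U1"),
                      base_quality=np.array(quals, dtype=int),
                      mapping_quality=np.array(mapqs, dtype=int),
                      repeat_flag=np.array(reps, dtype=bool),
                      dist_5prime=np.array(d5s, dtype=int),
                      dist_3prime=np.array(d3s, dtype=int),
                      strand=np.array(strands, dtype="U1"))


def build_site(tumor_reads, normal_reads, ref="A", chrom="chr1", pos=100,
               pair_id="p1") -> PairedSite:
    tumor = build_pileup(f"{pair_id}_T", chrom, pos, ref, tumor_reads)
    normal = build_pileup(f"{pair_id}_N", chrom, pos, ref, normal_reads)
    return PairedSite(pair_id, chrom, pos, ref, tumor, normal)


@pytest.fixture(scope="session")
def toy_genome():
    """A 10-gene toy genome shared by annotation and simulation tests."""
    config = simulate.SimConfig(seed=11, n_chromosomes=2, chrom_length=20_000,
                                n_genes=10)
    genome, models = simulate.make_genome(config)
    return config, genome, models
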