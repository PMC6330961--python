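import numpy as np
import pytest

from cdrcanon import CdrRecord, LoopGroup, generate_group, preset_scenarios


@pytest.fixture(scope="session")
def presets():
    return preset_scenarios(seed=17)


@pytest.fixture(scope="session")
def cis_group(presets):
    return generate_group(presets["CIS_MARKER"])


@pytest.fixture(scope="session")
def dominant_group(presets):
    return generate_group(presets["DOMINANT"])


@pytest.fixture(scope="session")
def inseparable_group(presets):
    return generate_group(presets["INSEPARABLE"])


def make_record(rid="rec1", loop_type="L2", loop_seq="ACDEFGHK",
                flank_up="GGGGGGGGGG", flank_down="SSSSSSSSSS",
                cluster=None, dihedrals=None):
    cluster = cluster or f"{loop_type}-{len(loop_seq)}-1"
    return CdrRecord(
        record_id=rid, loop_type=loop_type, loop_length=len(loop_seq),
        loop_seq=loop_seq, flank_up=flank_up, flank_down=flank_down,
        cluster_label=cluster, dihedrals=dihedrals,
    )


def random_dihedrals(rng, length):
    return tuple(
        (float(rng.uniform(-179.9, 180)), float(rng.uniform(-179.9, 180)))
        for _ in range(length)
    )


def dihedral_record(rid, dihedrals, loop_type="L2", cluster=None, rng=None):
    length = len(dihedrals)
    seq = "A" * length
    return CdrRecord(
        record_id=rid, loop_type=loop_type, loop_length=length,
        loop_seq=seq, cluster_label=cluster or f"{loop_type}-{length}-1",
        dihedrals=tuple(dihedrals),
    )
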