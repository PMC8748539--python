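import hypothesis
import pytest

from retroscope.config import PipelineConfig
from retroscope.model import (
    Caller,
    ConsensusInsertion,
    Gene,
    GeneSet,
    TECall,
    TEFamily,
    Tissue,
    Transcript,
)
from retroscope.pipeline import run_all
from retroscope.simulate import SimParams, generate_cohort

hypothesis.settings.register_profile(
    "ci", hypothesis.settings(derandomize=True, max_examples=50, deadline=None)
)
hypothesis.settings.load_profile("ci")


def mk_call(
    pos,
    chrom="chr1",
    family=TEFamily.ALU,
    caller=Caller.PRIMARY,
    patient="P001",
    tissue=Tissue.TUMOR,
    **kw,
):
    return TECall(
        patient_id=patient,
        sample_id=f"{patient}_{tissue.value}",
        tissue=tissue,
        chrom=chrom,
        pos=pos,
        te_family=family,
        caller=caller,
        **kw,
    )


def mk_cons(
    pos,
    chrom="chr1",
    family=TEFamily.ALU,
    patient="P001",
    tissue=Tissue.TUMOR,
    secondary_pos=None,
    **kw,
):
    return ConsensusInsertion(
        patient_id=patient,
        sample_id=f"{patient}_{tissue.value}",
        tissue=tissue,
        chrom=chrom,
        final_pos=pos,
        te_family=family,
        subfamily=kw.pop("subfamily", None),
        tsd_sequence=kw.pop("tsd_sequence", None),
        primary_pos=pos,
        secondary_pos=secondary_pos if secondary_pos is not None else pos,
        **kw,
    )


def mk_gene(gene_id, chrom, start, end, strand="+", exons=None, cds=None, name=None):
    return Gene(
        gene_id=gene_id,
        name=name or gene_id,
        chrom=chrom,
        strand=strand,
        transcripts=[
            Transcript(
                f"{gene_id}.t1",
                start,
                end,
                exons=list(exons or []),
                cds=list(cds or []),
            )
        ],
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The generator's default study conditions (39 noisy patients)."""
    out = tmp_path_factory.mktemp("bundle_default")
    truth = generate_cohort(SimParams(), seed=11, out_dir=out)
    return out, truth


@pytest.fixture(scope="session")
def default_results(default_bundle, tmp_path_factory):
    bundle, _ = default_bundle
    out = tmp_path_factory.mktemp("reports_default")
    return run_all(bundle, out, PipelineConfig())


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """20 patients, ~100 insertions each, no caller noise, jitter 30 bp."""
    out = tmp_path_factory.mktemp("bundle_noiseless")
    params = SimParams(
        n_patients=20,
        germline_rate=95.0,
        fn_rate_primary=0.0,
        fn_rate_secondary=0.0,
        fp_rate_primary=0.0,
        fp_rate_secondary=0.0,
    )
    truth = generate_cohort(params, seed=5, out_dir=out)
    return out, truth
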