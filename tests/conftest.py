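import pytest

from stescan import SynthSpec, generate_annotated_genome

#: composition of the recently-masculinized M. galloprovincialis LUR (T,C,G,A)
RM_FREQS = (0.282, 0.158, 0.209, 0.350)


@pytest.fixture
def simple_genome():
    """Small circular genome: one planted perfect motif copy in the LUR."""
    spec = SynthSpec(
        seed=11,
        lur_length=1200,
        lur_freqs=RM_FREQS,
        planted_copies=[(22, "+", 400)],
        genome_id="simple",
    )
    return generate_annotated_genome(spec)
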