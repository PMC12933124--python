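import pytest

from cryoet_census import (
    CellEntry,
    Domain,
    Freezing,
    Kingdom,
    Sectioning,
    Shape,
)


def make_entry(**overrides) -> CellEntry:
    """A valid plunge-frozen unsectioned bacterium, overridable per test."""
    base = dict(
        taxon_name="Escherichia coli",
        domain=Domain.BACTERIA,
        shape=Shape.CAPSULE,
        length_um=2.0,
        width_um=1.0,
        freezing=Freezing.PLUNGE,
        sectioning=Sectioning.NONE,
        year=2020,
        source_ref="test",
    )
    base.update(overrides)
    return CellEntry(**base)


@pytest.fixture
def toy_entries() -> list[CellEntry]:
    """Small mixed-domain table exercising every optional field."""
    return [
        make_entry(),
        make_entry(taxon_name="Caulobacter crescentus", length_um=2.5,
                   width_um=0.7, sectioning=Sectioning.FIB_SEM),
        make_entry(taxon_name="Sulfolobus acidocaldarius", domain=Domain.ARCHAEA,
                   shape=Shape.SPHERE, length_um=1.0, width_um=1.0),
        make_entry(taxon_name="Saccharomyces cerevisiae", domain=Domain.EUKARYOTA,
                   kingdom=Kingdom.FUNGI, shape=Shape.SPHERE, length_um=5.0,
                   width_um=5.0, sectioning=Sectioning.FIB_SEM),
        make_entry(taxon_name="HeLa", domain=Domain.EUKARYOTA,
                   kingdom=Kingdom.ANIMALIA, is_cell_line=True,
                   shape=Shape.SPHERE, length_um=17.0, width_um=17.0,
                   sectioning=Sectioning.FIB_SEM),
        make_entry(taxon_name="Caenorhabditis elegans", domain=Domain.EUKARYOTA,
                   kingdom=Kingdom.ANIMALIA, shape=Shape.CAPSULE,
                   length_um=50.0, width_um=30.0, freezing=Freezing.HPF,
                   sectioning=Sectioning.SERIAL_LIFT_OUT, cryoprotectant=True,
                   cryoprotectant_chemistry="glycerol"),
        make_entry(taxon_name="Homo sapiens brain", domain=Domain.EUKARYOTA,
                   kingdom=Kingdom.ANIMALIA, shape=Shape.RECTANGLE,
                   length_um=2000.0, width_um=100.0, extra_length_um=500.0,
                   freezing=Freezing.PLUNGE, sectioning=Sectioning.ULTRAMICROTOME,
                   cryoprotectant=True, cryoprotectant_chemistry="sucrose"),
    ]
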