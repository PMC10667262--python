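"""Variant parsing, mature numbering, classification and complex alleles."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gba1pd.variants import (
    AmbiguousPhaseWarning,
    ClassSource,
    GbaVariant,
    HgvsParseError,
    Severity,
    VariantClass,
    carrier_class,
    classify_variant,
    collapse_carrier_events,
    detect_complex_alleles,
    load_catalog,
    parse_hgvs_p,
    to_mature_numbering,
)


@pytest.mark.parametrize(
    "text, ref, pos, alt",
    [
        ("p.L483P", "L", 483, "P"),
        ("p.R398*", "R", 398, "*"),
        ("p.R398X", "R", 398, "*"),
        ("p.T408T", "T", 408, "T"),
        ("p.Leu483Pro", "L", 483, "P"),
        ("p.Arg398Ter", "R", 398, "*"),
        ("p.(K13R)", "K", 13, "R"),
    ],
)
def test_parse_hgvs_p(text, ref, pos, alt):
    site = parse_hgvs_p(text)
    assert (site.ref, site.position, site.alt) == (ref, pos, alt)
    assert site.is_synonymous == (ref == alt)
    assert site.is_stop_gain == (alt == "*")


@pytest.mark.parametrize(
    "bad", ["L483P", "p.483L", "p.L0P", "p.*483P", "c.1448T>C", "p.Xyz483Pro", ""]
)
def test_parse_hgvs_p_rejects_malformed(bad):
    with pytest.raises(HgvsParseError):
        parse_hgvs_p(bad)


@pytest.mark.parametrize("full, mature", [(483, 444), (40, 1), (495, 456), (499, 460)])
def test_mature_numbering_offset(full, mature):
    # p.L483P is the legacy L444P of the Gaucher literature
    assert to_mature_numbering(full) == mature


def test_signal_peptide_positions_unmapped():
    assert to_mature_numbering(13) is None
    assert to_mature_numbering(39) is None
    with pytest.raises(ValueError):
        to_mature_numbering(0)


@given(st.integers(min_value=40, max_value=600))
def test_mature_numbering_bijective(pos):
    mature = to_mature_numbering(pos)
    assert mature == pos - 39 and mature >= 1


def test_catalog_contains_reported_variants(catalog):
    # every variant of the study's distribution table resolves to a class
    expected = {
        "c.115+1G>A": Severity.SEVERE,
        "p.P161S": Severity.SEVERE,
        "p.G234W": Severity.SEVERE,
        "p.G241R": Severity.SEVERE,
        "p.H294Q": Severity.SEVERE,
        "p.R398*": Severity.SEVERE,
        "p.G416S": Severity.SEVERE,
        "p.L483P": Severity.SEVERE,
        "p.R502H": Severity.SEVERE,
        "p.N409S": Severity.MILD,
        "p.E365K": Severity.RISK,
        "p.T408M": Severity.RISK,
        "p.K13R": Severity.VUS,
        "p.Y61H": Severity.VUS,
        "p.R78C": Severity.VUS,
        "p.A97G": Severity.VUS,
        "p.L213P": Severity.VUS,
        "p.A215D": Severity.VUS,
        "p.E427K": Severity.VUS,
        "p.R434C": Severity.VUS,
        "p.H529R": Severity.VUS,
        "p.R534C": Severity.VUS,
        "p.A495P": Severity.VUS,
        "p.T408T": Severity.VUS,
    }
    for key, severity in expected.items():
        assert catalog.get(key).severity is severity, key
    rec = catalog.complex_allele("RecNciI")
    assert rec.components == {"p.L483P", "p.A495P", "p.V499V"}
    assert rec.severity.severity is Severity.SEVERE


def test_catalog_rejects_unknown_class(tmp_path):
    bad = tmp_path / "cat.tsv"
    bad.write_text("hgvs_p\thgvs_c\trsid\tclass\tsource\np.L483P\t\t\tlethal\thoglinger\n")
    with pytest.raises(ValueError, match="unknown severity class"):
        load_catalog(table_path=bad)


def test_classification_branches(catalog):
    assert classify_variant(GbaVariant(hgvs_p="p.L483P"), catalog).severity is Severity.SEVERE
    assert classify_variant(GbaVariant(hgvs_p="p.E365K"), catalog).severity is Severity.RISK
    # novel missense without ClinVar evidence falls through to VUS
    novel = classify_variant(GbaVariant(hgvs_p="p.Q123W"), catalog)
    assert novel == VariantClass(Severity.VUS, ClassSource.UNKNOWN)
    # novel exonic + ClinVar pathogenic -> severe via the fallback
    fallback = classify_variant(GbaVariant(hgvs_p="p.Q123W"), catalog, clinvar_label="Pathogenic")
    assert fallback == VariantClass(Severity.SEVERE, ClassSource.CLINVAR_FALLBACK)
    # synonymous outside splice regions stays unclassified
    syn = classify_variant(GbaVariant(hgvs_p="p.P171P"), catalog)
    assert syn.severity is Severity.SYNONYMOUS_UNCLASSIFIED


def test_catalog_hit_overrides_clinvar(catalog):
    # p.E365K stays a risk variant whatever ClinVar says
    klass = classify_variant(GbaVariant(hgvs_p="p.E365K"), catalog, clinvar_label="Pathogenic")
    assert klass.severity is Severity.RISK
    assert klass.source is ClassSource.HOGLINGER


def _phased(names, phase="hap1"):
    return [GbaVariant(hgvs_p=n, phase_group=phase) for n in names]


def test_complex_allele_requires_full_phased_set(catalog):
    full = _phased(["p.L483P", "p.A495P", "p.V499V"])
    assert [a.name for a in detect_complex_alleles(full, catalog)] == ["RecNciI"]
    # strict subsets never fire
    partial = _phased(["p.A495P", "p.V499V"])
    assert detect_complex_alleles(partial, catalog) == []
    single = _phased(["p.L483P"])
    assert detect_complex_alleles(single, catalog) == []
    # components split across haplotypes do not form the allele
    split = _phased(["p.L483P", "p.A495P"]) + _phased(["p.V499V"], phase="hap2")
    assert detect_complex_alleles(split, catalog) == []


def test_unphased_multivariant_warns_and_abstains(catalog):
    variants = [GbaVariant(hgvs_p="p.L483P"), GbaVariant(hgvs_p="p.A495P"),
                GbaVariant(hgvs_p="p.V499V")]
    with pytest.warns(AmbiguousPhaseWarning):
        assert detect_complex_alleles(variants, catalog) == []


def test_collapse_carrier_events(catalog):
    events = collapse_carrier_events(_phased(["p.L483P", "p.A495P", "p.V499V"]), catalog)
    assert events == {"RecNciI"}
    events = collapse_carrier_events(_phased(["p.A495P", "p.V499V"]), catalog)
    assert events == {"p.A495P", "p.V499V"}


def test_carrier_class_takes_maximum_severity():
    mild = VariantClass(Severity.MILD)
    severe = VariantClass(Severity.SEVERE)
    risk = VariantClass(Severity.RISK)
    vus = VariantClass(Severity.VUS)
    # p.N409S + p.L483P carriers are counted as severe
    assert carrier_class([mild, severe]).severity is Severity.SEVERE
    # homozygous risk stays risk (duplication changes nothing)
    assert carrier_class([risk, risk]).severity is Severity.RISK
    assert carrier_class([vus, risk]).severity is Severity.RISK
    with pytest.raises(ValueError):
        carrier_class([])


@settings(deadline=None)
@given(
    st.lists(
        st.sampled_from([Severity.SEVERE, Severity.MILD, Severity.RISK,
                         Severity.VUS, Severity.BENIGN]),
        min_size=1, max_size=6,
    )
)
def test_carrier_class_order_and_duplication_invariant(severities):
    classes = [VariantClass(s) for s in severities]
    forward = carrier_class(classes).severity
    assert forward == carrier_class(list(reversed(classes))).severity
    assert forward == carrier_class(classes + classes).severity
    assert forward == max(severities)
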