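"""RDES <-> RDML interchange over the supported subset."""

import zipfile

import pytest
from xml.etree import ElementTree as ET

from rdes.rdml import RDML_NAMESPACE, RDML_VERSION, RdmlError, from_rdml, to_rdml
from rdes.synth import simulate_amplification, simulate_melt

MINIMAL = """<rdml xmlns="http://www.rdml.org" version="1.2">
  <sample id="s1"><type>unkn</type></sample>
  <target id="g1"><type>toi</type><dyeId id="SYBR"/></target>
  <experiment id="e"><run id="r">
    <pcrFormat><rows>8</rows><columns>12</columns></pcrFormat>
    <react id="1"><sample id="s1"/>
      <data><tar id="g1"/><cq>2.5</cq>
        <adp><cyc>1</cyc><fluor>1.0</fluor></adp>
        <adp><cyc>2</cyc><fluor>2.0</fluor></adp>
        <adp><cyc>3</cyc><fluor>4.0</fluor></adp>
      </data>
    </react>
  </run></experiment>
</rdml>"""


class TestFromRdml:
    def test_minimal_document(self):
        amp, melt = from_rdml(MINIMAL)
        assert melt is None
        assert len(amp.records) == 1
        rec = amp.records[0]
        assert rec.well_id == "A1" and rec.sample == "s1"
        assert rec.target == "g1" and rec.dye == "SYBR"
        assert rec.reported_cq == 2.5
        assert list(amp.axis) == [1.0, 2.0, 3.0]
        assert list(rec.trace) == [1.0, 2.0, 4.0]

    def test_mdp_only_document_yields_melt_only(self):
        doc = MINIMAL.replace(
            "<adp><cyc>1</cyc><fluor>1.0</fluor></adp>",
            "<mdp><tmp>60.0</tmp><fluor>5.0</fluor></mdp>"
            "<mdp><tmp>60.5</tmp><fluor>4.0</fluor></mdp>").replace(
            "<adp><cyc>2</cyc><fluor>2.0</fluor></adp>", "").replace(
            "<adp><cyc>3</cyc><fluor>4.0</fluor></adp>", "")
        amp, melt = from_rdml(doc)
        assert amp is None and melt is not None
        assert melt.variant == "melt"
        assert list(melt.axis) == [60.0, 60.5]

    def test_unresolved_sample_reference(self):
        with pytest.raises(RdmlError, match="sample"):
            from_rdml(MINIMAL.replace('<react id="1"><sample id="s1"/>',
                                      '<react id="1"><sample id="ghost"/>'))

    def test_non_monotone_data_points(self):
        doc = MINIMAL.replace("<cyc>3</cyc>", "<cyc>2</cyc>")
        with pytest.raises(RdmlError, match="increasing"):
            from_rdml(doc)

    def test_ragged_cycle_lists_fail_axis_unification(self):
        extra = """<react id="2"><sample id="s1"/>
          <data><tar id="g1"/>
            <adp><cyc>1</cyc><fluor>1.0</fluor></adp>
            <adp><cyc>2</cyc><fluor>2.0</fluor></adp>
          </data></react>"""
        doc = MINIMAL.replace("</react>", "</react>" + extra, 1)
        with pytest.raises(RdmlError, match="axis unification"):
            from_rdml(doc)

    def test_unsupported_elements_warn_not_fail(self):
        doc = MINIMAL.replace("<sample id=\"s1\">",
                              "<experimenter id=\"x\"/><sample id=\"s1\">")
        amp, _ = from_rdml(doc)
        assert any("experimenter" in w for w in amp.meta["warnings"])


class TestToRdml:
    def test_react_and_adp_counts_for_table1(self, table1_infilled):
        xml = to_rdml(table1_infilled)
        root = ET.fromstring(xml)
        ns = {"r": RDML_NAMESPACE}
        reacts = root.findall(".//r:react", ns)
        assert len(reacts) == 12
        for react in reacts:
            assert len(react.findall(".//r:adp", ns)) == 45

    def test_no_melt_means_no_mdp(self, small_plate):
        plate, _ = small_plate
        assert "<mdp>" not in to_rdml(plate)

    def test_declared_namespace_and_version(self, small_plate):
        plate, _ = small_plate
        root = ET.fromstring(to_rdml(plate))
        assert root.tag == f"{{{RDML_NAMESPACE}}}rdml"
        assert root.get("version") == RDML_VERSION

    def test_mismatched_well_sets_rejected(self):
        amp, _ = simulate_amplification(samples=3, targets=1, seed=1)
        melt, _ = simulate_melt(samples=2, targets=1, seed=1)
        with pytest.raises(RdmlError, match="differ"):
            to_rdml(amp, melt)


class TestRoundTrip:
    def test_amp_round_trip(self, small_plate):
        plate, _ = small_plate
        amp, melt = from_rdml(to_rdml(plate))
        assert melt is None
        assert amp.equals(plate)

    def test_amp_plus_melt_round_trip(self):
        amp, _ = simulate_amplification(samples=3, targets=2, seed=13)
        melt, _ = simulate_melt(samples=3, targets=2, seed=13)
        amp2, melt2 = from_rdml(to_rdml(amp, melt))
        assert amp2.equals(amp)
        assert melt2.equals(melt)

    def test_zip_container_accepted(self, tmp_path):
        plate, _ = simulate_amplification(samples=2, targets=1, seed=14)
        xml = to_rdml(plate)
        path = tmp_path / "run.rdml"
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("rdml_data.xml", xml)
        amp, _ = from_rdml(path)
        assert amp.equals(plate)
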