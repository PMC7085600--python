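"""Template database contents, expansion and persistence."""

import json

import pytest

from throwsense import builtin_db, compress_runs, expand_template, load_db, save_db
from throwsense.encode import FOREARM_ALPHABET, UPPERARM_ALPHABET


class TestBuiltinContents:
    def test_thirteen_ordered_sub_templates(self, db):
        assert len(db.sub_templates) == 13
        assert [t.id for t in db.sub_templates] == [
            "Step 1", "Steps 1-2", "Step 2.1", "Step 2.2", "Steps 2-3",
            "Step 3.1", "Step 3.2", "Steps 3-4", "Step 4.1", "Step 4.2",
            "Step 4.3", "Step 5", "Step 6",
        ]

    def test_step1_sub_template_classes(self, db):
        t = db.sub_templates[0]
        assert list(t.forearm_classes) == ["E", "P"]
        assert list(t.upper_classes) == ["p"]

    def test_phase_template_classes(self, db):
        assert list(db.phase_templates[2].forearm_classes) == ["Y", "M", "A"]
        assert list(db.phase_templates[4].forearm_classes) == ["D", "L", "F", "M"]
        assert list(db.phase_templates[4].upper_classes) == ["r", "y"]

    def test_error_catalogue(self, db):
        assert "No follow-through" in db.errors_for(6)
        assert "Elbow is not high enough" in db.errors_for(4)
        assert db.errors_for(0) == ["Worn too inside or outside"]
        for k in range(1, 7):
            assert db.errors_for(k)

    def test_every_template_symbol_is_in_its_channel_alphabet(self, db):
        for t in list(db.phase_templates.values()) + db.sub_templates:
            assert all(c in FOREARM_ALPHABET for c in t.forearm_classes)
            assert all(c in UPPERARM_ALPHABET for c in t.upper_classes)

    def test_sub_templates_chain_head_to_tail_in_temporal_order(self, db):
        """Read temporally, consecutive templates overlap by one class on
        both channels — the structural consistency of the 13-entry list."""
        subs = db.sub_templates
        for prev, nxt in zip(subs, subs[1:]):
            assert prev.temporal_forearm[-1] == nxt.temporal_forearm[0]
            assert prev.temporal_upper[-1] == nxt.temporal_upper[0]


class TestExpand:
    def test_step1_expansion(self, db):
        fore, up = expand_template(db.sub_templates[0], (2, 2))
        assert fore == "EEPP"
        assert up == "pppp"

    def test_all_lengths_one_gives_minimal_string(self, db):
        t = db.sub_templates[3]  # two classes per channel
        fore, up = expand_template(t, (1, 1))
        assert fore == "".join(t.forearm_classes)
        assert len(up) == 2

    def test_expand_then_compress_recovers_class_list(self, db):
        for t in db.sub_templates:
            fore, up = expand_template(t, tuple(3 for _ in t.forearm_classes))
            assert compress_runs(fore).symbols == list(t.forearm_classes)
            assert compress_runs(up).symbols == list(t.upper_classes)
            assert len(fore) == len(up)

    def test_rejects_bad_run_lengths(self, db):
        with pytest.raises(ValueError):
            expand_template(db.sub_templates[0], (2,))
        with pytest.raises(ValueError):
            expand_template(db.sub_templates[0], (2, 0))


class TestPersistence:
    def test_save_load_round_trip(self, db, tmp_path):
        path = tmp_path / "db.json"
        save_db(db, path)
        loaded = load_db(path)
        assert loaded.sub_templates == db.sub_templates
        assert loaded.phase_templates == db.phase_templates
        assert loaded.error_defs == db.error_defs
        assert loaded.deviants == db.deviants

    def test_reordered_sub_templates_survive_reload(self, db, tmp_path):
        path = tmp_path / "db.json"
        save_db(db, path)
        payload = json.loads(path.read_text())
        payload["sub_templates"] = payload["sub_templates"][::-1]
        path.write_text(json.dumps(payload))
        loaded = load_db(path)
        assert [t.id for t in loaded.sub_templates] == [t.id for t in db.sub_templates][::-1]

    def test_unknown_symbol_error_names_the_symbol(self, db, tmp_path):
        path = tmp_path / "db.json"
        save_db(db, path)
        payload = json.loads(path.read_text())
        payload["sub_templates"][0]["forearm"] = ["@", "P"]
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="'@'"):
            load_db(path)

    def test_malformed_json_rejected(self, tmp_path):
        path = tmp_path / "db.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            load_db(path)
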