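"""Action-table compilation, validation, and virtual-clock execution."""

import numpy as np
import pytest

from simscope import (
    ActionEvent,
    ActionTable,
    ChannelSpec,
    CompileError,
    ExperimentSpec,
    ValidationError,
    compile_experiment,
    execute_table,
    read_dv,
    run_experiment,
    validate_table,
)

CAM_LINE, LIGHT_LINE, Z_LINE = "D0", "D3", "A1"


def make_spec(t=1, c=1, z=1, z_start=0.0, z_step=1.0, interval_ms=0.0,
              exposure_ms=10.0, save_path=""):
    channels = tuple(
        ChannelSpec(
            name=f"ch{i}",
            light_handler="laser:source",
            camera_handler="camera:camera",
            filter_position=i,
            exposure_ms=exposure_ms,
        )
        for i in range(c)
    )
    return ExperimentSpec(
        channels=channels, z_start_um=z_start, z_step_um=z_step,
        n_slices=z, n_timepoints=t, interval_ms=interval_ms,
        save_path=save_path,
    )


def z_levels_visited(table):
    return [ev.value for ev in table.events if ev.line == Z_LINE]


def test_minimal_experiment_has_one_of_each(sim_depot):
    table = compile_experiment(make_spec(), sim_depot)
    assert len(table.rising_edges(CAM_LINE)) == 1
    assert len(table.rising_edges(LIGHT_LINE)) == 1
    assert len(z_levels_visited(table)) == 1


def test_edge_count_and_z_staircase(sim_depot):
    table = compile_experiment(make_spec(t=3, c=2, z=5, z_step=0.5), sim_depot)
    assert len(table.rising_edges(CAM_LINE)) == 30
    per_tp = len(z_levels_visited(table)) // 3
    assert per_tp == 5
    assert sorted(set(z_levels_visited(table))) == [0.0, 0.5, 1.0, 1.5, 2.0]


def test_z_levels_are_an_arithmetic_progression():
    spec = make_spec(z=3, z_start=10.0, z_step=0.5)
    assert spec.z_levels() == [10.0, 10.5, 11.0]


def test_empty_channel_list_rejected():
    with pytest.raises(ValidationError):
        ExperimentSpec(channels=())


def test_unresolvable_handler_is_a_compile_error(sim_depot):
    spec = make_spec()
    bad = ExperimentSpec(
        channels=(ChannelSpec(name="x", light_handler="ghost:light",
                              camera_handler="camera:camera"),),
    )
    with pytest.raises(CompileError, match="ghost:light"):
        compile_experiment(bad, sim_depot)
    assert compile_experiment(spec, sim_depot)  # control: valid spec compiles


def test_validate_accepts_empty_and_flags_backwards_time():
    assert validate_table(ActionTable()).ok
    table = ActionTable(events=[
        ActionEvent(10, "A0", 1.0), ActionEvent(5, "A0", 2.0)
    ])
    # construction sorts; force disorder to exercise the check
    table.events = [ActionEvent(10, "A0", 1.0), ActionEvent(5, "A0", 2.0)]
    report = validate_table(table)
    assert any("non-monotonic" in v for v in report.violations)


def test_compiled_tables_validate_cleanly_for_random_specs(sim_depot):
    rng = np.random.default_rng(17)
    for _ in range(60):
        t, c, z = rng.integers(1, 6), rng.integers(1, 4), rng.integers(1, 21)
        spec = make_spec(t=int(t), c=int(c), z=int(z),
                         z_step=float(rng.uniform(0.1, 2.0)),
                         exposure_ms=float(rng.uniform(1, 50)))
        table = compile_experiment(spec, sim_depot)
        assert validate_table(table).ok
        assert len(table.rising_edges(CAM_LINE)) == t * c * z
        levels_per_tp = len(z_levels_visited(table)) // t
        assert levels_per_tp == z


def test_compile_is_deterministic(sim_depot, tmp_path):
    spec = make_spec(t=2, c=3, z=4)
    a = compile_experiment(spec, sim_depot)
    b = compile_experiment(spec, sim_depot)
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    a.to_tsv(pa)
    b.to_tsv(pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_execute_yields_one_image_per_trigger_with_full_index_coverage(sim_depot):
    table = compile_experiment(make_spec(t=2, c=2, z=3, z_step=5.0), sim_depot)
    results = execute_table(table, sim_depot)
    assert len(results) == 12
    seen = {(r.t_index, r.c_index, r.z_index) for r in results}
    assert seen == {(t, c, z) for t in range(2) for c in range(2) for z in range(3)}
    stamps = [r.timestamp_us for r in results]
    assert stamps == sorted(stamps)


def test_defocused_slices_differ(sim_depot):
    table = compile_experiment(make_spec(z=2, z_step=8.0), sim_depot)
    results = execute_table(table, sim_depot)
    by_z = {r.z_index: r.image for r in results}
    assert not np.array_equal(by_z[0], by_z[1])


def test_run_experiment_shape_and_round_trip(sim_depot, tmp_path):
    path = tmp_path / "exp.dv"
    spec = make_spec(t=1, c=3, z=8, save_path=str(path))
    dataset = run_experiment(spec, sim_depot)
    assert dataset.shape == (1, 3, 8, 512, 512)
    back = read_dv(path)
    assert np.array_equal(back.data, dataset.data)
    assert back.exposures_ms == [10.0, 10.0, 10.0]


def test_zero_interval_timepoints_are_volume_spaced(sim_depot):
    table = compile_experiment(make_spec(t=3, c=1, z=2), sim_depot)
    cam_rises = table.rising_edges(CAM_LINE)
    # first shot of each timepoint: shots are ordered t-major
    starts = [s.time_us for s in table.shots if s.z_index == 0 and s.c_index == 0]
    volume = starts[1] - starts[0]
    assert starts[2] - starts[1] == volume
    assert len(cam_rises) == 6


def test_short_interval_warns_and_still_schedules(sim_depot):
    spec = make_spec(t=2, c=1, z=5, interval_ms=1.0)
    with pytest.warns(UserWarning, match="shorter than one volume"):
        table = compile_experiment(spec, sim_depot)
    assert len(table.rising_edges(CAM_LINE)) == 10


def test_all_digital_lines_end_low(sim_depot):
    table = compile_experiment(make_spec(t=2, c=2, z=2), sim_depot)
    levels = {}
    for ev in table.events:
        if ev.line.startswith("D"):
            levels[ev.line] = ev.value
    assert levels and not any(levels.values())
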