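"""Run-folder dialect, round trips and streaming/batch equivalence."""

import numpy as np
import pytest

from lampcall import RunConfig, builtin_dye, standard_layout
from lampcall.run_io import (
    AVG_CSV_NAME,
    CALLS_CSV_NAME,
    PARAMS_NAME,
    RAW_CSV_NAME,
    RunProcessor,
    analyze_folder,
    discover_frames,
    load_frames,
    process_run,
    read_params,
    read_run_folder,
    write_params,
    write_run_folder,
)
from lampcall.calling import HueSeries, call_plate
from lampcall.synthetic import (
    NoiseModel,
    frames_for_run,
    generate_run,
    random_truths,
)


@pytest.fixture(scope="module")
def synthetic_folder(tmp_path_factory):
    """A 10-min PR run folder with 5 known positives at moderate noise."""
    cfg = RunConfig(run_name="fixture", total_assay_min=10.0, interval_s=60.0)
    dye = builtin_dye("PR")
    layout = standard_layout(360, 240)
    truths = random_truths(cfg, 5, rng=11)
    folder, _ = generate_run(
        cfg, truths, dye, noise=NoiseModel(rgb_sd=1.5, seed=11),
        path=tmp_path_factory.mktemp("runs") / "fixture", layout=layout,
    )
    return cfg, layout, truths, folder


def test_config_validation():
    with pytest.raises(ValueError):
        RunConfig(total_assay_min=10, interval_s=70)  # does not divide evenly
    with pytest.raises(ValueError):
        RunConfig(n_reactions=0)
    assert RunConfig(total_assay_min=60, interval_s=60).n_frames == 61


def test_params_round_trip(tmp_path):
    cfg = RunConfig(run_name="r1", total_assay_min=30, interval_s=30,
                    assay_temperature_C=63.0, n_reactions=54, dye="HNB")
    layout = standard_layout(640, 480)
    write_params(tmp_path / "params.txt", cfg, layout)
    cfg2, layout2, _ = read_params(tmp_path / "params.txt")
    assert cfg2 == cfg
    assert layout2 == layout


def test_params_unknown_keys_warn(tmp_path):
    (tmp_path / "params.txt").write_text("run_name=x\nmystery_knob=1\n")
    with pytest.warns(UserWarning, match="mystery_knob"):
        cfg, _, _ = read_params(tmp_path / "params.txt")
    assert cfg.run_name == "x"


def test_frame_discovery_gap_raises(tmp_path, synthetic_folder):
    _, _, _, folder = synthetic_folder
    import shutil
    dst = tmp_path / "gappy"
    shutil.copytree(folder, dst)
    (dst / "Image_3.png").unlink()
    with pytest.raises(FileNotFoundError, match="Image_3"):
        discover_frames(dst)


def test_analyze_recovers_truth(synthetic_folder):
    cfg, layout, truths, folder = synthetic_folder
    record = analyze_folder(folder)
    assert len(record.series) == 96
    assert len(record.calls) == 96
    called = {w for w, c in record.calls.items() if c.status == "positive"}
    assert called == {t.well for t in truths if t.is_positive}


def test_streaming_equals_batch(synthetic_folder, tmp_path):
    cfg, layout, _, folder = synthetic_folder
    dye = builtin_dye(cfg.dye)
    batch = process_run(cfg, load_frames(folder, cfg.interval_s), dye=dye, layout=layout)
    stream = RunProcessor(cfg, layout, dye=dye)
    for frame in load_frames(folder, cfg.interval_s):
        stream.feed(frame)
    srec = stream.finalize()
    assert srec.call_history == batch.call_history
    for w in batch.series:
        assert np.array_equal(srec.series[w].raw, batch.series[w].raw)
        assert srec.calls[w] == batch.calls[w]
    # byte-identical CSV output
    batch.frames = srec.frames = []
    write_run_folder(batch, tmp_path / "a")
    write_run_folder(srec, tmp_path / "b")
    for name in (RAW_CSV_NAME, AVG_CSV_NAME, CALLS_CSV_NAME, PARAMS_NAME):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_run_folder_round_trip_byte_identical(synthetic_folder, tmp_path):
    cfg, layout, _, folder = synthetic_folder
    record = analyze_folder(folder)
    record.frames = list(discover_frames(folder))
    write_run_folder(record, tmp_path / "first")
    reread = read_run_folder(tmp_path / "first")
    assert reread.config == record.config
    assert reread.layout == record.layout
    for w in record.series:
        assert np.array_equal(reread.series[w].raw, record.series[w].raw)
        assert reread.calls[w].status == record.calls[w].status
    write_run_folder(reread, tmp_path / "second")
    for name in (RAW_CSV_NAME, AVG_CSV_NAME, CALLS_CSV_NAME, PARAMS_NAME):
        assert (tmp_path / "first" / name).read_bytes() == (
            tmp_path / "second" / name
        ).read_bytes()


def test_write_refuses_existing_folder(synthetic_folder, tmp_path):
    cfg, layout, _, folder = synthetic_folder
    record = analyze_folder(folder)
    record.frames = []
    write_run_folder(record, tmp_path / "once")
    with pytest.raises(FileExistsError):
        write_run_folder(record, tmp_path / "once")
    write_run_folder(record, tmp_path / "once", overwrite=True)


def test_calls_csv_consistent_with_raw_csv(synthetic_folder, tmp_path):
    """Recomputing calls from the raw CSV alone reproduces the calls CSV."""
    cfg, layout, _, folder = synthetic_folder
    record = analyze_folder(folder, out=tmp_path / "out")
    from lampcall.run_io import _read_hue_csv

    times, wells, raw = _read_hue_csv(tmp_path / "out" / RAW_CSV_NAME)
    series = [HueSeries(well=w, times=times, raw=raw[w]) for w in wells]
    recomputed = call_plate(series, builtin_dye(cfg.dye))
    calls_lines = (tmp_path / "out" / CALLS_CSV_NAME).read_text().splitlines()[1:]
    for line in calls_lines:
        well_s, status, *_ = line.split(",")
        from lampcall import WellID
        assert recomputed[WellID.parse(well_s)].status == status


def test_frame_count_mismatch_raises(synthetic_folder):
    cfg, layout, _, folder = synthetic_folder
    frames = list(load_frames(folder, cfg.interval_s))[:-2]
    with pytest.raises(ValueError, match="frames"):
        process_run(cfg, frames, dye=builtin_dye("PR"), layout=layout)


def test_raster_size_mismatch_raises(synthetic_folder):
    cfg, layout, _, folder = synthetic_folder
    wrong_layout = standard_layout(480, 320)
    proc = RunProcessor(cfg, wrong_layout, dye=builtin_dye("PR"))
    frame = next(iter(load_frames(folder, cfg.interval_s)))
    with pytest.raises(ValueError, match="does not match"):
        proc.feed(frame)


def test_partial_plate_run_produces_96_series(tmp_path):
    """A run with only 54 loaded wells still yields 96 callable series;
    unloaded wells see flat background and come out negative."""
    cfg = RunConfig(run_name="partial", total_assay_min=6.0, interval_s=60.0,
                    n_reactions=54)
    dye = builtin_dye("PR")
    layout = standard_layout(360, 240)
    truths = [t for t in random_truths(cfg, 3, rng=2)][:54]
    record = process_run(
        cfg, frames_for_run(cfg, truths, dye, layout, NoiseModel(rgb_sd=0.0)),
        dye=dye, layout=layout,
    )
    assert len(record.series) == 96
    assert len(record.calls) == 96
    loaded = {t.well for t in truths}
    for w, c in record.calls.items():
        if w not in loaded:
            assert c.status == "negative"
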