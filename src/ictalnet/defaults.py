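"""Shared defaults for the whole pipeline.

Values that the study design fixes (sampling rate, segment length, channel
count, EEG band edges, STE threshold, Kuramoto coupling constant) live here
so that every stage and the CLI agree on them.
"""

#: Sampling rate of the scalp EEG recordings (Hz).
RATE = 256

#: Number of scalp channels in the standard 10-20 bipolar montage used.
N_CHANNELS = 23

#: Analysis window length (seconds); all downstream stages operate on
#: non-overlapping windows of this length.
SEGMENT_SECONDS = 10

#: Samples per segment.
SEGMENT_SAMPLES = RATE * SEGMENT_SECONDS

#: Conventional EEG frequency bands (Hz).
BANDS = {
    "delta": (0.5, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
}

#: Band order used wherever band weights appear as a 4-vector.
BAND_ORDER = ("delta", "theta", "alpha", "beta")

#: Band-pass edges applied during preprocessing (Hz).
FILTER_LO = 0.5
FILTER_HI = 40.0

#: Hilbert-spectrum display/analysis range (Hz) and grid resolution.
HS_FREQ_RANGE = (0.0, 40.0)
HS_N_FREQ_BINS = 80
HS_N_TIME_BINS = 100

#: Directed-network edge threshold on symbolic transfer entropy (bits).
STE_THRESHOLD = 0.02
#: Sparser threshold used for display-quality network figures.
STE_DISPLAY_THRESHOLD = 0.08

#: Kuramoto coupling constant.
KURAMOTO_K = 3.5

#: Lag (samples) of the cross-channel linear mixing used by the synthetic
#: generator to realize directed coupling.
COUPLING_LAG = 4

#: Standard 23-channel bipolar montage channel labels (10-20 system),
#: as found in typical pediatric scalp EEG recordings.
CHANNEL_NAMES = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
    "P7-T7", "T7-FT9", "FT9-FT10", "FT10-T8", "T8-P8-1",
)
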