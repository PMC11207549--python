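# Methods

## Detection systems and coordinate convention

Two detection-system geometries are built in: the GM grid (13 rows × 5
columns, one missing corner electrode, 64 physical electrodes, 8-mm
inter-electrode distance) and the SO arrays (1 × 8 electrodes, 5-mm
inter-electrode distance, one over the medial and one over the lateral
exposed portion of soleus). All modules share one lattice convention:
0-based `(row, col)`, row 0 most proximal, column 0 most medial. A recording
stores the *full* derived-montage lattice channel-major, with a per-channel
validity mask; positions without a physical electrode, and derived channels
touching one, are zero-filled and invalid. Invalid channels are excluded
from every map, ratio and statistic — never imputed — so the fixed
channel ↔ (row, col) bijection survives every processing stage.

## Montages

*Single-differential (SD):* output channel `(r, c) = monopolar(r+1, c) −
monopolar(r, c)`, i.e. the difference of consecutive rows within a column —
the spatial filter along the fibre (proximal–distal) direction. The GM grid
yields a 12 × 5 SD lattice with 59 valid channels (the one SD channel
touching the missing corner is invalid). The 1-row SO arrays cannot be
differentiated across rows; the only in-array option, the
adjacent-electrode differential along the array (7 channels from 8
electrodes), is selected with `axis="cols"` (or `"auto"`); requesting
`axis="rows"` on a single-row array is an error by contract.

*Simulated bipolar:* two disjoint, contiguous 3 × 3 electrode groups are
each averaged (mimicking ~2 cm² electrodes) and subtracted, producing one
channel. The default placement puts both blocks on the grid's middle
column, block centres at rows 4 and 8 (one skipped row between the blocks);
the exact published placement is not printed anywhere we know of, so the
default is explicit and overridable per call and per pipeline config. Both
montages are linear and null a spatially uniform field exactly — the test
suite asserts both properties.

## Synthetic EMG model

Each channel carries `field(ch) × n_ch(t) + crosstalk × s(t) + noise ×
w_ch(t)` where `n_ch` are independent unit-RMS band-limited Gaussian
processes, `s` is one shared unit-RMS process (crosstalk from a distant
muscle arrives through the volume conductor with essentially equal
amplitude everywhere, hence spatially uniform), and `w_ch` is white sensor
noise. The band-limiting is a 4th-order zero-phase Butterworth band-pass
(default 20–350 Hz at 2048 Hz) applied to white noise, followed by exact
per-channel unit-RMS rescaling, which makes the planted per-channel RMS
`sqrt(field² + crosstalk² + noise²)` exact rather than asymptotic. The
spatial field is a non-negative base plus Gaussian blobs on the lattice.

This is deliberately an amplitude-modulated-noise model, not a motor-unit
simulator: every downstream quantity in the package depends only on the
per-channel RMS structure, which the model controls exactly. What passing
tests show is therefore that the *estimation chain* is correct under known
amplitude structure; they do not probe motor-unit-level phenomena (firing
statistics, action-potential propagation, nonstationarity of real maximal
efforts, electrode–skin artefacts), and real recordings will add dispersion
the synthetic studies do not contain.

Default study conditions: 5-s trials at 2048 Hz, 1 µV sensor noise, no
crosstalk, agonist fields of ~20–170 µV RMS — amplitudes and durations
typical of surface EMG of the calf during isometric effort. Torque traces
plateau at 100 % or 30 % of MVC; submaximal noise is clipped to the
±5 %-MVC target band by construction, mirroring the visual-feedback
protocol. Per-trial seeds are derived by folding a stable SHA-256 hash of
the `(subject, muscle, knee, effort, direction)` tuple into the study
master seed (kept below 2³¹), so studies regenerate byte-identically while
trials remain mutually independent.

## Amplitude and CAN estimation

RMS is computed per channel either over the whole recording (submaximal
trials, which hold a steady plateau) or over a 500-ms epoch centred at the
peak of the rectified signal (maximal trials, where peak drive may be
brief). The peak is located per channel independently on the raw rectified
signal — channel-wise processing is the reading most consistent with
computing every quantity "for each channel separately"; no smoothing
envelope is applied by default. Epochs hitting a recording boundary are
shifted inward to preserve the window length, and the bounds actually used
are recorded.

CAN ratios: BipCAN divides the single bipolar antagonist RMS by the bipolar
agonist-MVC RMS; CsCAN divides channel-wise; OvCAN divides every channel by
the maximum valid agonist-MVC RMS of the detection system (each SO array is
its own detection system and is normalized independently). The MVC
reference always shares the knee position of the antagonist trial, since
knee angle changes gastrocnemius architecture and cross-position
normalization would conflate the two effects. A zero agonist denominator
invalidates the affected channel (with a logged warning) rather than
failing the run; an all-invalid or zero bipolar reference is an error.
Values above 1 are meaningful (antagonist drive exceeding the channel's own
agonist maximum) and are never clipped.

In the ground-truth validation studies (`coactmap.validation`) both sides
of the ratio use the whole-recording RMS: the synthetic signals are
stationary, so the full 5-s window is the tightest per-channel estimate,
and it keeps the max-over-grid denominator of the overall scheme
essentially unbiased (with 500-ms epochs the ~5 % per-channel dispersion
would inflate the 59-channel maximum by ~10 %, a property of the
max-denominator estimator rather than a defect of the pipeline).

## Spatial analysis

Only channels over the superficial aponeurosis enter the spatial stage; the
mask is an explicit input (known exactly for synthetic data; identifying it
from action-potential propagation on real signals is out of scope).
Segmentation keeps channels at or above 70 % of the map maximum (over
included, valid channels) and returns the largest 4-connected component;
ties are broken by higher summed CAN, then by the most
proximal-then-medial component. The threshold is relative, making the
segmentation invariant to positive rescaling of the map; both the fraction
and the connectivity are configurable. The centroid is the CAN-weighted
mean lattice position of the segmented channels (unweighted mean as a
logged fallback for an all-zero mask). The proximal–distal coordinate is
normalized to the aponeurosis row span (0 = most proximal, 1 = most
distal); the medial–lateral coordinate to the full column span, since only
the longitudinal axis has an anatomical reference length. Relative
segmented size is the segmented count over the included-and-valid count.

## Pipeline and reporting

`run_pipeline` walks a dataset directory (the binary+JSON-sidecar trial
format), derives montages, forms the knee-matched CAN maps per subject ×
condition × scheme, segments the GM maps, and writes per-trial maps, a
long-format per-trial table, and pooled descriptive tables (means ± SDs
across subjects). Pooling across conditions uses equal cell weights
(identical to pooling trials directly in a balanced design) and reports at
two decimals with round-half-up — the convention under which per-cell and
pooled means stay mutually consistent. Every run logs the package version,
config hash and per-channel invalidation counts; reruns are byte-identical.
Inferential statistics (ANOVA, post hoc corrections) are intentionally
absent — the long-format table is the export point for external
statistical software.

## Validation studies and problem sizes

`scripts/acceptance.py` (and the mirrored acceptance tests) recompute, at
run time: the pooled worked examples from published condition-cell means;
the OvCAN ≤ CsCAN dominance over 200 randomized map pairs (with equality
exactly for uniform agonist maps); recovery of planted
antagonist-to-agonist ratios α ∈ {0.3, 0.5, 1.2} from 20 seeds of 5-s
trials per α (uniform fields, so all three schemes share the target;
α = 1.2 additionally checks unclipped CAN > 100 %); hotspot localization
with the antagonist blob at (3, 1) and the agonist blob at (9, 3), scored
as the overall-scheme centroid falling within one inter-electrode distance
of the plant, plus the projection of the channel-specific-vs-overall
centroid displacement onto the antagonist-minus-agonist direction (positive
when the channel-specific centroid is repelled from the agonist hotspot);
and the 59-channel SD bookkeeping of the GM grid. These ensemble sizes keep
the whole validation run under a minute on one core while leaving the
Monte-Carlo error well inside the stated tolerances (per-channel RMS
dispersion of a 5-s band-limited trial is ~1–2 %, verified in the test
suite against an independent FFT-based implementation).

## Known limitations

* No motor-unit, conduction-velocity or volume-conductor physics; synthetic
  validation speaks to the estimation chain, not to physiological realism.
* The aponeurosis mask must be supplied for real data.
* Only lattice layouts (grids/arrays) are supported; no irregular montages.
* The simulated-bipolar placement is a documented default, not an
  anatomically individualized choice.
* Descriptive statistics only; no inferential testing.
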