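"""Re-derive the trigger and impact thresholds from calibration falls.

Collects the ASVM trough (loss-of-balance minimum) and peak (ground-impact
maximum) from 100 simulated falls, fits a normal approximation to each, and
prints the mean ± 3·SD bounds next to the observed extremes — the numbers a
designer rounds into deployed thresholds (trough bound widened upward to
800 mg; peak bound narrowed downward to 1400 mg).
"""

from fallfsm import calibrate, extract_peak, extract_trough, generate_fall

troughs, peaks = [], []
for seed in range(100):
    st = generate_fall("fall_forward", seed=seed)
    gt = st.ground_truth
    troughs.append(extract_trough(
        st.trace, (gt["a2_start"] + 1, gt["trough_index"] + 1)))
    peaks.append(extract_peak(
        st.trace, (gt["trough_index"] + 2, gt["a4_start"] + 1)))

for name, values, tail in [("trough", troughs, "lower"),
                           ("peak", peaks, "upper")]:
    s = calibrate(values, tail=tail)
    bound = s.mean_plus_3sd if tail == "lower" else s.mean_minus_3sd
    print(f"{name}: n={s.n}  mean={s.mean:.2f} mg  sd={s.sd:.2f} mg")
    print(f"  mean {'+' if tail == 'lower' else '-'} 3*SD = {bound:.2f} mg, "
          f"observed range [{s.observed_min:.1f}, {s.observed_max:.1f}] mg")
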