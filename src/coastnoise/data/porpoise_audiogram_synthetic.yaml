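# Synthetic harbour-porpoise audiogram.
#
# Representative U-shaped hearing thresholds (dB re 1 uPa) at decidecade
# centre frequencies, composited to the shape of published behavioural
# audiograms for Phocoena phocoena: poor sensitivity below ~1 kHz, best
# hearing around 100 kHz, rising again towards the upper limit. These are
# stand-in values for development and testing, not a digitisation of any
# single published study; replace with a measured audiogram for real
# analyses.
frequencies_hz:   [125,  250,  500, 1000, 2000, 4000, 8000, 16000, 31500, 63000, 125000]
threshold_db:     [104,  100,   92,   79,   66,   57,   51,    45,    39,    35,    41]
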