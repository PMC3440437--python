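"""Resource models: data compression and computational load.

Shows what the counting-and-comparison decoder saves: the ratio of the raw
digitized input bit rate to the decoder's binary output bit rate, and the
operations-per-second budget of the internal unit.
"""

from countdec import CompressionInputs, OpCountModel, compression_factor, op_count

# 32 channels digitized to 8 bits at 10 kHz, decoding 32 states every 100 ms
inputs = CompressionInputs(N=32, B=8, f_s=10_000, K=32, W=0.1)
print(f"input bit rate      : {inputs.N * inputs.B * inputs.f_s:,.0f} bit/s")
print(f"output bit rate     : {inputs.K / inputs.W:,.0f} bit/s")
print(f"compression factor  : {compression_factor(inputs):,.0f}")

# operation accounting for 32 templates of M=2 thresholds, one comparison's
# worth of logic per threshold, at 10 computational frames per second
model = OpCountModel.for_configuration(K_T=32, M=2, K=32, b_logic=1, frame_rate=10.0)
print(f"operations per frame : {model.ops_per_frame:,.0f}")
for cat, n in sorted(model.tallies.items()):
    print(f"  {cat:24s} {n:6.0f}")
print(f"operations per second: {op_count(model):,.0f}")

# Decoding reduces a 2.56 Mbit/s recording stream to 320 bit/s — a factor of
# 8000 — while the implanted unit itself needs only a few thousand counting,
# comparison and register operations per second.
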