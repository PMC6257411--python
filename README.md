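# spinnlite

A desk-scale, pure-software emulator of the event-driven runtime used by
digital neuromorphic hardware to simulate spiking neural networks (SNNs) in
realtime.  It reproduces, on an ordinary workstation, the numerical and
structural machinery of such a platform:

* **s16.15 fixed-point arithmetic** ("accum"): every on-core quantity is a
  signed 32-bit integer worth `raw / 2**15`, with wrap-on-overflow and
  underflow-to-zero semantics, and a shift-based codec between 16-bit
  ring-buffer integers and accum weights;
* **bit-exact synaptic data structures**: 32-bit static synapse words
  (16-bit weight | 4-bit delay | type bit | 8-bit neuron id), padded
  synaptic rows with static/plastic regions, and the two-level
  master-population-table / address-list lookup from a masked spike key to
  matrix rows;
* **the event-driven spike pipeline**: packet-received → user →
  row-processing callbacks with priorities −1…2, a 256-entry input spike
  buffer, and per-neuron, per-receptor 16-slot ring buffers of saturating
  16-bit accumulators;
* **neuron models on fixed-point state**: current/conductance LIF via exact
  exponential integration, and the Izhikevich model via an RK-2 midpoint
  step;
* **graph preprocessing**: partitioning populations into ≤255-neuron
  machine vertices, connector-aware machine-edge generation, power-of-two
  routing-key allocation, and automatic delay-extension vertices for
  synaptic delays of 17–144 timesteps;
* **an analytic throughput model** predicting how many synaptic events a
  core can absorb per timer period.

Who it is for: anyone studying how SNN simulators interact with
fixed-point arithmetic and event-driven scheduling — without hardware —
and anyone who wants the platform's worked numbers to be checkable by
running code.

## The core model

A core simulating `n` neurons has a virtual budget `t_p` µs per timer
period (1000 µs for a 1 ms timestep in realtime).  Updating the neurons
costs `m_n·n + c_n`; a spike targeting `nP` neurons costs a per-word slope
plus a fixed overhead, with separate coefficients for the first (`f`),
subsequent (`s`) and last (`l`) spikes of an active pipeline.  The number
of synaptic events (spike × target pairs) a core can process per period is

```
E_s = nP · ( [t_p − (m_n n + c_n) − (m_sf nP + c_sf) − (m_sl nP + c_sl)]
             / (m_ss nP + c_ss)  +  2 )
```

Neuron dynamics (current-based LIF, exact integration over one step Δt):

```
V_{t+1} = E_l + R_m I_{t+Δt} − e^(−Δt/τ_m) (E_l + R_m I_{t+Δt} − V_t)
I_{t+1} = I_t e^(−Δt/τ_syn) + Σ_j w_ij δ(t − t_j)
```

with `V > V_θ` ⇒ spike, `V ← V_reset`, refractory for `t_r`.  All of this
runs in s16.15 with host-precomputed decay constants.

## Worked example

```python
import spinnlite as sl

pred = sl.predict_events(128, 1.0)           # LIF preset, t_p = 1000 µs
print(pred.events)                           # -> 5922

print(sl.encode_weight(1.15, 6))             # -> 589
print(float(sl.decode_ring_value(589, 6)))   # -> 1.150390625

net = sl.build_balanced_fixture(seed=1)      # 500 exc + 125 inh LIF,
res = sl.run(net, 2000.0, seed=1)            # 250×50 Hz Poisson, stimulus @1 s
print(round(res.rate_hz("excitatory", 500, 1000), 1))    # -> 21.9
print(round(res.rate_hz("excitatory", 1000, 1200), 1))   # -> 26.4
```

The first number is the cost model's peak: a core running 128 fully
connected LIF neurons can absorb 5,922 synaptic events in one 1 ms period.
The codec lines show the fixed-point round trip of a 1.15 nA weight at
ring-buffer shift 6: stored as the integer 589, it reads back as
1.150390625 nA (the half-LSB quantisation is visible).  The last two lines
run the random balanced network for 2 s of model time: a stable ~22 Hz
excitatory regime that jumps to ~26 Hz in the 200 ms after the prescribed
spike-array stimulus at t = 1 s.  All randomness flows from the seed, so
these numbers are bit-reproducible.

A CLI wraps the same functionality:

```sh
spinnlite run --duration 2000 --seed 1 --out-dir out/   # fixture run → CSVs
spinnlite netgen --seed 1                               # machine-graph manifest
spinnlite costmodel --n 128 --p 1.0                     # → 5922 events
spinnlite inspect out/matrix.bin --json                 # decode a matrix dump
```

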