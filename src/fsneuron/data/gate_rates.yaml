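# Voltage-dependent rate coefficients for the Hodgkin-Huxley-style gates of
# the FS interneuron model: Na activation (m, instantaneous), Na inactivation
# (h), Kv1 activation (n1, fourth power) and Kv3 activation (n3, squared).
#
# Transcribed from the fast-spiking neocortical interneuron model of
# Erisir, Lau, Rudy & Leonard (1999), J. Neurophysiol. 82:2476-2489, as used
# by Mancilla et al. (2007), J. Neurosci. 27:2058-2073.  The Na-inactivation
# (h) rates carry a x2 kinetic (temperature-compensation) factor relative to
# the root source, fixed while validating this transcription against the
# striatal FS model's reference behaviour (resting state, Hopf current,
# firing rates); see docs/methods.md.
#
# Templates (V in mV, rates in ms^-1):
#   linoid:      C * (V - V_half) / (exp((V - V_half)/s) - 1); limit C*s at V_half
#   exponential: C * exp((V - V_half)/s)
#   sigmoid:     C / (1 + exp(-(V - V_half)/s))
#   constant:    C
version: 2
source: >-
  Erisir A, Lau D, Rudy B, Leonard CS (1999) Function of specific K+ channels
  in sustained high-frequency firing of fast-spiking neocortical interneurons.
  J Neurophysiol 82:2476-2489 (via Mancilla JG et al. 2007, J Neurosci 27:2058);
  h rates scaled x2 (temperature compensation, fixed during model validation).
gates:
  m:
    alpha: {template: linoid, C: -40.0, V_half: 75.5, s: -13.5}
    beta: {template: exponential, C: 1.2262, V_half: 0.0, s: -42.248}
  h:
    alpha: {template: exponential, C: 0.007, V_half: 0.0, s: -24.186}
    beta: {template: linoid, C: -0.034, V_half: -51.25, s: -5.2}
  n1:
    alpha: {template: linoid, C: -0.014, V_half: -44.0, s: -2.3}
    beta: {template: exponential, C: 0.0043, V_half: -44.0, s: -34.0}
  n3:
    alpha: {template: linoid, C: -1.0, V_half: 95.0, s: -11.8}
    beta: {template: exponential, C: 0.025, V_half: 0.0, s: -22.222}
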