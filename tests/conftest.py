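from hypothesis import HealthCheck, settings

# fixed profile: reproducible runs, no flaky deadline failures on shared CI
settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")
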