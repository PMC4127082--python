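MITOCHONDRION_LIKE	synthetic demo set: energy-metabolism themed	GENE001	GENE002	GENE003	GENE004	GENE005	GENE006	GENE007	GENE008	GENE009	GENE010
INFLAMMATORY_RESPONSE_LIKE	synthetic demo set: immune-response themed	GENE011	GENE012	GENE013	GENE014	GENE015	GENE016	GENE017	GENE018
ZINC_FINGER_LIKE	synthetic demo set: transcription-factor themed	GENE019	GENE020	GENE021	GENE022	GENE023	GENE024
HOUSEKEEPING_LIKE	synthetic demo set: broadly expressed background	GENE001	GENE011	GENE019	GENE025	GENE026	GENE027	GENE028	GENE029	GENE030
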