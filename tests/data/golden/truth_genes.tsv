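gene	essential	fitness	interaction_class	interaction_effect	essentiality_prior
G0001	False	0.0	none	0.0	-0.02833277661467938
G0002	False	0.0	none	0.0	-0.01896726948638997
G0003	False	0.0	none	0.0	0.07878652562816002
G0004	False	0.0	none	0.0	-0.06317694762645086
G0005	False	0.0	none	0.0	0.002538752762426174
G0006	False	0.0	none	0.0	0.02434134344748543
G0007	False	0.0	none	0.0	-0.03371446257971656
G0008	False	0.0	none	0.0	0.043149765977695494
G0009	False	0.0	none	0.0	0.0322957997501623
G0010	True	-0.3	none	0.0	-0.30011134214701995
G0011	True	-0.3	none	0.0	-0.18527131299824282
G0012	False	0.0	none	0.0	0.05160877886464665
G0013	True	-0.3	none	0.0	-0.21322457524404165
G0014	False	0.0	suppressor	0.4	-0.0024717488612048854
G0015	False	0.0	none	0.0	-0.08792409434735769
G0016	False	0.0	none	0.0	0.050626857391526
G0017	True	-0.3	none	0.0	-0.4291544972148146
G0018	False	0.0	none	0.0	-0.03430597954375927
G0019	False	0.0	none	0.0	0.03506472494309727
G0020	False	0.0	none	0.0	-4.599730155610856e-05
G0021	False	0.0	none	0.0	0.09121093318513226
G0022	False	0.0	none	0.0	0.07637953125666436
G0023	False	0.0	none	0.0	-0.012560695612192361
G0024	False	0.0	none	0.0	-0.012680258999995747
G0025	False	0.0	none	0.0	0.019109745577748073
G0026	False	0.0	none	0.0	-0.00863618193949387
G0027	False	0.0	none	0.0	0.10395310788990175
G0028	False	0.0	enhancer	-0.4	-0.008974260669370527
G0029	False	0.0	enhancer	-0.4	-0.07184345192478857
G0030	False	0.0	none	0.0	0.05103199369637262
G0031	True	-0.3	none	0.0	-0.22908868338691873
G0032	False	0.0	none	0.0	0.03438783326181718
G0033	False	0.0	none	0.0	0.022261124481630885
G0034	True	-0.3	none	0.0	-0.2867435255185567
G0035	False	0.0	none	0.0	-0.03703115587109634
G0036	False	0.0	suppressor	0.4	0.020592691743285377
G0037	False	0.0	none	0.0	0.056264722617226565
G0038	True	-0.3	none	0.0	-0.30693329908968364
G0039	False	0.0	enhancer	-0.4	-0.04285208989158495
G0040	True	-0.3	none	0.0	-0.1103980834402142
CTRL	False	0.0	none	0.0	0.034960104522654016
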