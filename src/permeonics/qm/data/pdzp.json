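{
 "name": "pdzp",
 "provenance": "permeonics internal double-zeta-plus-polarization basis; even-tempered primitives optimized variationally (H: exact one-electron atom; O: closed-shell water; Ca: closed-shell Ca2+), general (ANO-style) contraction from atomic orbital vectors; polarization exponents fixed a priori (O d 0.85, H p 0.80, Ca d 1.0/0.25). Built by scripts/build_basis.py.",
 "elements": {
  "H": [
   {
    "l": 0,
    "exp": [
     9.117103539379054,
     2.2377587121504914,
     0.5492494444289792,
     0.1348112066629525
    ],
    "coef": [
     -0.024695066931342508,
     -0.09501982509266409,
     -0.4340139006108453,
     -0.5808862557609048
    ]
   },
   {
    "l": 0,
    "exp": [
     0.1348112066629525
    ],
    "coef": [
     1.0
    ]
   },
   {
    "l": 1,
    "exp": [
     0.8
    ],
    "coef": [
     1.0
    ]
   }
  ],
  "O": [
   {
    "l": 0,
    "exp": [
     4170.348374126155,
     1287.939274826238,
     397.7575556832262,
     122.84047563068513,
     37.93713592002873,
     11.716221989743095,
     3.618350578765455,
     1.1174643944365366,
     0.3451093656213568
    ],
    "coef": [
     0.0020017390558970233,
     0.005010707294695891,
     0.02530418653852051,
     0.09444190259466578,
     0.30810151927142343,
     0.5310258140967943,
     0.19619696989345228,
     -0.01247054144096769,
     0.005234856494889785
    ]
   },
   {
    "l": 0,
    "exp": [
     4170.348374126155,
     1287.939274826238,
     397.7575556832262,
     122.84047563068513,
     37.93713592002873,
     11.716221989743095,
     3.618350578765455,
     1.1174643944365366,
     0.3451093656213568
    ],
    "coef": [
     0.00045554215258801885,
     0.0011940100686642723,
     0.005776507080979127,
     0.023328372091093834,
     0.07985942973706797,
     0.20219069981895071,
     0.09899325846733945,
     -0.5174576262377342,
     -0.626434601980785
    ]
   },
   {
    "l": 0,
    "exp": [
     0.3451093656213568
    ],
    "coef": [
     1.0
    ]
   },
   {
    "l": 1,
    "exp": [
     27.50346175604279,
     7.902862809588194,
     2.2708138030460887,
     0.6524971332981223,
     0.18748895589376796
    ],
    "coef": [
     0.025836328156512958,
     0.1253195234799559,
     0.4601879637831653,
     0.7216597604145243,
     0.5010606044878216
    ]
   },
   {
    "l": 1,
    "exp": [
     0.18748895589376796
    ],
    "coef": [
     1.0
    ]
   },
   {
    "l": 2,
    "exp": [
     0.85
    ],
    "coef": [
     1.0
    ]
   }
  ],
  "Ca": [
   {
    "l": 0,
    "exp": [
     47120.333691329746,
     16539.042532570496,
     5805.135627562585,
     2037.578631775781,
     715.1816851542638,
     251.02581799963508,
     88.10902545525039,
     30.925904070493843,
     10.854864613877027,
     3.810012652080186,
     1.3372987066511506,
     0.4693863233851545
    ],
    "coef": [
     0.0009841807698497543,
     0.0016770488104936414,
     0.00838783334254003,
     0.02794995953294703,
     0.09560399343673867,
     0.27041762972574107,
     0.4813233569744376,
     0.26111225165124347,
     -0.0013919855492711786,
     0.007726364138572591,
     -0.0037365538412627145,
     0.0011056287258297344
    ]
   },
   {
    "l": 0,
    "exp": [
     47120.333691329746,
     16539.042532570496,
     5805.135627562585,
     2037.578631775781,
     715.1816851542638,
     251.02581799963508,
     88.10902545525039,
     30.925904070493843,
     10.854864613877027,
     3.810012652080186,
     1.3372987066511506,
     0.4693863233851545
    ],
    "coef": [
     -0.0002855420263216104,
     -0.0004900109479314259,
     -0.002445480199944089,
     -0.008306610408687385,
     -0.029354527560655853,
     -0.09251217654243477,
     -0.21762230853397885,
     -0.1901317155295324,
     0.5189391522188718,
     0.6562650810504964,
     0.012293767732341167,
     0.010535956024966122
    ]
   },
   {
    "l": 0,
    "exp": [
     47120.333691329746,
     16539.042532570496,
     5805.135627562585,
     2037.578631775781,
     715.1816851542638,
     251.02581799963508,
     88.10902545525039,
     30.925904070493843,
     10.854864613877027,
     3.810012652080186,
     1.3372987066511506,
     0.4693863233851545
    ],
    "coef": [
     9.849629120114619e-05,
     0.00016943411269724167,
     0.0008435709791989738,
     0.0028762947482620033,
     0.010181908208227028,
     0.03251714172526578,
     0.07872578990795566,
     0.07495967237013323,
     -0.2484643382853142,
     -0.5610165038203598,
     0.4603818716077165,
     0.8343956320461654
    ]
   },
   {
    "l": 0,
    "exp": [
     0.4693863233851545
    ],
    "coef": [
     1.0
    ]
   },
   {
    "l": 1,
    "exp": [
     495.86162571958624,
     177.84065017984526,
     63.782505473161166,
     22.875579909991156,
     8.204321111822512,
     2.9424777501049415,
     1.055318921804038,
     0.3784898719040162
    ],
    "coef": [
     -0.008582042844414429,
     -0.03322182031335318,
     -0.15946534642286697,
     -0.49520555594601473,
     -0.787165784930577,
     -0.32935952762319015,
     0.005101997466915159,
     -0.005587312987700212
    ]
   },
   {
    "l": 1,
    "exp": [
     495.86162571958624,
     177.84065017984526,
     63.782505473161166,
     22.875579909991156,
     8.204321111822512,
     2.9424777501049415,
     1.055318921804038,
     0.3784898719040162
    ],
    "coef": [
     -0.0023917551620435073,
     -0.009033901334296095,
     -0.04592003091850295,
     -0.14477912283319944,
     -0.2593896586688208,
     0.06336924763550872,
     0.7500359369335926,
     0.5856538749329251
    ]
   },
   {
    "l": 1,
    "exp": [
     0.3784898719040162
    ],
    "coef": [
     1.0
    ]
   },
   {
    "l": 2,
    "exp": [
     1.0
    ],
    "coef": [
     1.0
    ]
   },
   {
    "l": 2,
    "exp": [
     0.25
    ],
    "coef": [
     1.0
    ]
   }
  ]
 }
}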