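! Synthetic STO-6G-style minimal reference basis.
! Generated by scripts/make_reference_basis.py: six-Gaussian
! least-squares refit of Slater orbitals (standard minimal-basis
! zeta values) on a radial grid. Not downloaded data.
****
H     0
S   6   1.00
       3.5523214272E+01        9.1635972966E-03
       6.5131433791E+00        4.9361493607E-02
       1.8221428837E+00        1.6853830350E-01
       6.2595526691E-01        3.7056279736E-01
       2.4307674801E-01        4.1649153027E-01
       1.0011242832E-01        1.3033408536E-01
****
He     0
S   6   1.00
       6.5984521881E+01        9.1636013943E-03
       1.2098193935E+01        4.9361508161E-02
       3.3846391276E+00        1.6853833181E-01
       1.1627149840E+00        3.7056281085E-01
       4.5151627896E-01        4.1649149415E-01
       1.8595934556E-01        1.3033406045E-01
****
C     0
S   6   1.00
       7.4271582544E+02        9.1638091740E-03
       1.3617800051E+02        4.9362099587E-02
       3.8097908234E+01        1.6853934959E-01
       1.3087701579E+01        3.7056329522E-01
       5.0823483523E+00        4.1649015738E-01
       2.0931949294E+00        1.3033306040E-01
S   6   1.00
       8.1903127182E+01       -4.1512799688E-03
       1.5020208653E+01       -2.0670243508E-02
       4.2210035130E+00       -5.1503029863E-02
       6.0361293474E-01        3.3462710274E-01
       2.7395667362E-01        5.6210613577E-01
       1.3064838884E-01        1.7129947997E-01
P   6   1.00
       1.7360736830E+01        7.9242338674E-03
       4.5273270731E+00        5.1441050687E-02
       1.6199207515E+00        1.8984001432E-01
       6.7715783863E-01        4.0498632588E-01
       3.0964269386E-01        4.0123627613E-01
       1.4638814137E-01        1.0518551115E-01
****
N     0
S   6   1.00
       1.0277808339E+03        9.1639417810E-03
       1.8844667493E+02        4.9362478500E-02
       5.2721062267E+01        1.6854000306E-01
       1.8111201870E+01        3.7056360438E-01
       7.0331340700E+00        4.1648929923E-01
       2.8966402318E+00        1.3033242184E-01
S   6   1.00
       1.0527194821E+02       -4.1512808843E-03
       1.9305819575E+01       -2.0670244354E-02
       5.4253533381E+00       -5.1503028353E-02
       7.7583768343E-01        3.3462709739E-01
       3.5212285678E-01        5.6210613785E-01
       1.6792539937E-01        1.7129948379E-01
P   6   1.00
       2.2314155614E+01        7.9242345041E-03
       5.8190781303E+00        5.1441051492E-02
       2.0821216360E+00        1.8984001090E-01
       8.7036665404E-01        4.0498631977E-01
       3.9799092707E-01        4.0123628016E-01
       1.8815606852E-01        1.0518551517E-01
****
O     0
S   6   1.00
       1.3554897318E+03        9.1641159131E-03
       2.4853586805E+02        4.9362973657E-02
       6.9532319898E+01        1.6854085316E-01
       2.3886415158E+01        3.7056400390E-01
       9.2758423453E+00        4.1648818108E-01
       3.8203184334E+00        1.3033159123E-01
S   6   1.00
       1.4015488110E+02       -4.1512823093E-03
       2.5703009641E+01       -2.0670245334E-02
       7.2231032401E+00       -5.1503026071E-02
       1.0329200003E+00        3.3462709316E-01
       4.6880262241E-01        5.6210614079E-01
       2.2356931924E-01        1.7129948569E-01
P   6   1.00
       2.9708195237E+01        7.9242345910E-03
       7.7472932642E+00        5.1441053098E-02
       2.7720553658E+00        1.8984001862E-01
       1.1587721381E+00        4.0498632869E-01
       5.2986956242E-01        4.0123627065E-01
       2.5050363591E-01        1.0518550637E-01
****
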